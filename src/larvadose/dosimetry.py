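"""Absorbed-power and SAR bookkeeping for larvae exposed in a chamber.

The electromagnetic dose to a larva is the whole-body absorbed power

    P_abs = sum_voxels sigma |E_int|^2 dV,

with sigma the conductivity [S/m], |E_int| the RMS internal field [V/m] and
dV the voxel volume.  Field solving is out of scope here: this module
consumes voxelized internal-field grids (or printed reference values) and
handles the surrounding arithmetic — quadratic rescaling of P_abs with the
incident field strength, whole-body SAR at tissue density 1000 kg/m^3,
field <-> plane-wave power-density conversion via S = E^2/377, plane-wave
exposure sets, and spheroid / mesh larva volumes.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .constants import C0, FIELD_HIGH_EXPOSURE, FIELD_LOW_EXPOSURE, RHO_TISSUE, Z0

__all__ = [
    "FieldGrid",
    "PlaneWave",
    "PlaneWaveSet",
    "DoseSummary",
    "absorbed_power",
    "scale_pabs",
    "whole_body_sar",
    "field_to_power_density",
    "power_density_to_field",
    "field_for_target_pabs",
    "wavelength",
    "build_plane_wave_set",
    "dose_summary",
    "spheroid_volume",
    "mesh_volume",
    "instar_dimensions",
    "REFERENCE_PABS_VERTICAL",
]

#: Reference whole-body absorbed powers [W] for the anatomical model in the
#: vertical (breathing) position at the loaded-chamber field strengths.  Two
#: internally consistent pairs circulate for L4 (results-figure vs summary
#: values); both are carried.
REFERENCE_PABS_VERTICAL = {
    ("L1", FIELD_LOW_EXPOSURE): 66.7e-9,
    ("L1", FIELD_HIGH_EXPOSURE): 1.04e-6,
    ("L4", FIELD_LOW_EXPOSURE): 8.36e-6,
    ("L4", FIELD_HIGH_EXPOSURE): 0.13e-3,
    ("L4-summary", FIELD_LOW_EXPOSURE): 7.19e-6,
    ("L4-summary", FIELD_HIGH_EXPOSURE): 1.12e-4,
}


@dataclass
class FieldGrid:
    """Voxelized RMS internal field with a conductivity and material map.

    Attributes
    ----------
    voxel_m : float
        Edge length of the (cubic) voxels [m].
    e_rms : ndarray
        Per-voxel RMS internal field magnitude [V/m].
    sigma : ndarray
        Per-voxel conductivity [S/m].
    materials : ndarray of str
        Material label per voxel (e.g. ``"larva"``, ``"water"``).
    """

    voxel_m: float
    e_rms: np.ndarray
    sigma: np.ndarray
    materials: np.ndarray

    def __post_init__(self) -> None:
        self.e_rms = np.asarray(self.e_rms, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.materials = np.asarray(self.materials)
        if self.voxel_m <= 0:
            raise ValueError("voxel edge length must be positive")
        if self.e_rms.shape != self.sigma.shape or self.e_rms.shape != self.materials.shape:
            raise ValueError("e_rms, sigma and materials must share a shape")
        if np.any(self.e_rms < 0) or np.any(self.sigma < 0):
            raise ValueError("field magnitudes and conductivities must be >= 0")

    @property
    def voxel_volume_m3(self) -> float:
        return self.voxel_m**3

    def to_csv(self, path: str | Path) -> None:
        """Write the grid as long-format CSV with a voxel-size header line."""
        flat_idx = np.ndindex(self.e_rms.shape)
        with open(path, "w", newline="") as fh:
            fh.write(f"# voxel_m={self.voxel_m!r} shape={'x'.join(map(str, self.e_rms.shape))}\n")
            w = csv.writer(fh)
            w.writerow(["i", "j", "k", "e_rms_v_per_m", "sigma_s_per_m", "material"])
            for idx in flat_idx:
                w.writerow([*idx, self.e_rms[idx], self.sigma[idx], self.materials[idx]])

    @classmethod
    def from_csv(cls, path: str | Path) -> "FieldGrid":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("#"):
                raise ValueError("grid CSV must start with a '# voxel_m=... shape=...' line")
            meta = dict(tok.split("=") for tok in header[1:].split())
            voxel_m = float(meta["voxel_m"])
            shape = tuple(int(s) for s in meta["shape"].split("x"))
            rows = list(csv.DictReader(fh))
        e = np.zeros(shape)
        s = np.zeros(shape)
        m = np.empty(shape, dtype=object)
        for r in rows:
            idx = tuple(int(r[k]) for k in ("i", "j", "k"))[: len(shape)]
            e[idx] = float(r["e_rms_v_per_m"])
            s[idx] = float(r["sigma_s_per_m"])
            m[idx] = r["material"]
        return cls(voxel_m=voxel_m, e_rms=e, sigma=s, materials=m.astype(str))


@dataclass(frozen=True)
class PlaneWave:
    """Incident plane wave: unit propagation direction and polarization."""

    direction: tuple[float, float, float]
    polarization: tuple[float, float, float]

    def __post_init__(self) -> None:
        d = np.asarray(self.direction)
        p = np.asarray(self.polarization)
        if not (np.isclose(np.linalg.norm(d), 1) and np.isclose(np.linalg.norm(p), 1)):
            raise ValueError("direction and polarization must be unit vectors")
        if abs(float(d @ p)) > 1e-9:
            raise ValueError("polarization must be orthogonal to propagation")


@dataclass
class PlaneWaveSet:
    label: str
    waves: list[PlaneWave]

    def __len__(self) -> int:
        return len(self.waves)

    @property
    def n_directions(self) -> int:
        return len({w.direction for w in self.waves})


@dataclass
class DoseSummary:
    """Plane-wave-averaged dose for one larva model at one incident field."""

    pabs_mean: float
    pabs_min: float
    pabs_max: float
    pabs_per_volume: float  # W/mm^3
    incident_field: float  # V/m
    sar: float  # W/kg
    volume_mm3: float
    condition: str

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def absorbed_power(grid: FieldGrid, mask: str = "larva") -> float:
    """Whole-body absorbed power [W]: sum of sigma |E|^2 dV over masked voxels."""
    sel = grid.materials == mask
    if not np.any(sel):
        raise ValueError(f"material mask {mask!r} selects no voxels")
    return float((grid.sigma[sel] * grid.e_rms[sel] ** 2).sum() * grid.voxel_volume_m3)


def scale_pabs(pabs_ref: float, e_ref: float, e_new: float) -> float:
    """Rescale absorbed power quadratically to a new incident field strength.

    P_abs is quadratic in the incident RMS field: simulations at 1 V/m (or
    any reference) rescale as ``(e_new / e_ref)^2``.
    """
    if e_ref <= 0:
        raise ValueError("reference field must be positive")
    if e_new < 0 or pabs_ref < 0:
        raise ValueError("fields and powers must be nonnegative")
    return pabs_ref * (e_new / e_ref) ** 2


def whole_body_sar(pabs_per_volume_w_mm3: float, rho: float = RHO_TISSUE) -> float:
    """Whole-body SAR [W/kg] from volume-normalized dose [W/mm^3].

    At rho = 1000 kg/m^3 (water and larva alike) 1 uW/mm^3 maps to 1 W/kg.
    """
    if pabs_per_volume_w_mm3 < 0:
        raise ValueError("dose must be nonnegative")
    return pabs_per_volume_w_mm3 * 1e9 / rho


def field_to_power_density(e_v_per_m: float) -> float:
    """Plane-wave power density S = E^2 / 377 [W/m^2]."""
    if e_v_per_m < 0:
        raise ValueError("field must be nonnegative")
    return e_v_per_m**2 / Z0


def power_density_to_field(s_w_per_m2: float) -> float:
    """Inverse conversion E = sqrt(377 S) [V/m]."""
    if s_w_per_m2 < 0:
        raise ValueError("power density must be nonnegative")
    return float(np.sqrt(Z0 * s_w_per_m2))


def field_for_target_pabs(pabs_at_1vpm: float, target_pabs: float) -> float:
    """Incident field [V/m] that yields a target absorbed power.

    Inverts the quadratic scaling from a known absorption at 1 V/m.
    """
    if pabs_at_1vpm <= 0 or target_pabs <= 0:
        raise ValueError("absorbed powers must be positive")
    return float(np.sqrt(target_pabs / pabs_at_1vpm))


def wavelength(f_hz: float) -> float:
    """Free-space wavelength [m]."""
    if f_hz <= 0:
        raise ValueError("frequency must be positive")
    return C0 / f_hz


def _orthonormal_pols(d: np.ndarray) -> list[tuple[float, ...]]:
    """Two deterministic orthonormal polarizations perpendicular to d."""
    ref = np.array([0.0, 0.0, 1.0])
    if abs(d @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    p1 = np.cross(d, ref)
    p1 /= np.linalg.norm(p1)
    p2 = np.cross(d, p1)
    p2 /= np.linalg.norm(p2)
    return [tuple(np.round(p1, 12)), tuple(np.round(p2, 12))]


def build_plane_wave_set(label: str = "canonical-12") -> PlaneWaveSet:
    """Construct the exposure-averaging plane-wave sets.

    ``canonical-12``: the 6 axis-aligned incidence directions, each with the
    two axis-aligned polarizations (12 waves).  ``extended``: adds incidence
    at 45/135 deg zenith for every 45 deg azimuth, plus the 90 deg zenith
    diagonal azimuths, for 26 directions x 2 polarizations = 52 waves.
    """
    axes = [
        (1.0, 0.0, 0.0), (-1.0, 0.0, 0.0),
        (0.0, 1.0, 0.0), (0.0, -1.0, 0.0),
        (0.0, 0.0, 1.0), (0.0, 0.0, -1.0),
    ]
    waves: list[PlaneWave] = []
    for d in axes:
        for p in _orthonormal_pols(np.array(d)):
            waves.append(PlaneWave(d, p))
    if label == "canonical-12":
        return PlaneWaveSet(label, waves)
    if label != "extended":
        raise ValueError(f"unknown plane-wave set label {label!r}")

    directions = {d for d in axes}
    for zen_deg in (45.0, 90.0, 135.0):
        for az_deg in range(0, 360, 45):
            zen, az = np.radians(zen_deg), np.radians(az_deg)
            d = (
                float(np.round(np.sin(zen) * np.cos(az), 12)),
                float(np.round(np.sin(zen) * np.sin(az), 12)),
                float(np.round(np.cos(zen), 12)),
            )
            directions.add(d)
    for d in sorted(directions):
        if d in axes:
            continue
        for p in _orthonormal_pols(np.array(d)):
            waves.append(PlaneWave(d, p))
    return PlaneWaveSet(label, waves)


def dose_summary(pabs_list, volume_mm3: float, incident_e: float) -> DoseSummary:
    """Summarize plane-wave P_abs values into the reported dose quantities.

    Mean/min/max over the plane-wave set, volume-normalized dose, whole-body
    SAR, and the exposure-condition label implied by the incident field
    (46.2 V/m -> LE, 182.6 V/m -> HE, else custom).
    """
    p = np.asarray(pabs_list, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one absorbed-power value")
    if volume_mm3 <= 0:
        raise ValueError("volume must be positive")
    if np.any(p < 0):
        raise ValueError("absorbed powers must be nonnegative")
    per_vol = float(p.mean() / volume_mm3)
    if np.isclose(incident_e, FIELD_LOW_EXPOSURE, atol=0.05):
        condition = "LE"
    elif np.isclose(incident_e, FIELD_HIGH_EXPOSURE, atol=0.05):
        condition = "HE"
    else:
        condition = "custom"
    return DoseSummary(
        pabs_mean=float(p.mean()),
        pabs_min=float(p.min()),
        pabs_max=float(p.max()),
        pabs_per_volume=per_vol,
        incident_field=float(incident_e),
        sar=whole_body_sar(per_vol),
        volume_mm3=float(volume_mm3),
        condition=condition,
    )


def spheroid_volume(length_m: float, width_m: float) -> float:
    """Volume [mm^3] of a prolate spheroid larva model.

    The spheroid has the larva's full body length as polar axis and the head
    width as equatorial diameter: V = (pi/6) L W^2.
    """
    if length_m <= 0 or width_m <= 0:
        raise ValueError("dimensions must be positive")
    return float(np.pi / 6.0 * length_m * width_m**2 * 1e9)


def mesh_volume(stl_path: str | Path) -> float:
    """Volume [mm^3 per mesh unit^3] of a closed STL mesh via signed tetrahedra."""
    import trimesh

    mesh = trimesh.load_mesh(str(stl_path))
    if not mesh.is_watertight:
        raise ValueError(f"mesh {stl_path} is not a closed manifold")
    return float(abs(mesh.volume))


def instar_dimensions(path: str | Path | None = None):
    """Spheroid model dimensions per larval instar.

    Reads the editable packaged CSV (synthetic placeholder values chosen to
    match the published per-instar volume scale) unless *path* points at a
    user table.  Returns ``{instar: (length_m, width_m, volume_mm3)}``.
    """
    if path is None:
        ref = resources.files("larvadose.data").joinpath("instar_dimensions.csv")
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    out = {}
    rows = [r for r in text.splitlines() if r.strip() and not r.startswith("#")]
    for rec in csv.DictReader(rows):
        length = float(rec["length_mm"]) * 1e-3
        width = float(rec["width_mm"]) * 1e-3
        out[int(rec["instar"])] = (length, width, spheroid_volume(length, width))
    return out
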