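"""Synthetic 4D beating-heart label phantom with closed-form ground truth.

The phantom stands in for ECG-gated breath-hold MRI segmentations: ten
cardiac structures rendered as analytic primitives (solid ellipsoids for
chambers, ellipsoid shells for myocardium, tubes for the coronary
branches) voxelised over a 20-phase cardiac cycle on an anisotropic grid
(5 mm slices along CC, finer in-plane — matching thoracic cine MR
geometry).

Motion model (per structure, per phase index t of n):

* contraction — an affine scale ``s(t) = 1 - a * (1 - cos(2*pi*t/n)) / 2``
  applied to all linear dimensions about the structure center, so the
  volume swings between ``V0`` (phase 0) and ``V0 * (1 - a)**3``;
* translation — ``tau(t) = A * (1 - cos(2*pi*t/n)) / 2`` per patient
  axis, so ``A`` is exactly the peak-to-peak centroid excursion (for
  even n).

The raised-cosine law is smooth, periodic, and has its extrema exactly
at phases 0 and n/2, which makes the per-cycle maxima/minima of volume
and position available in closed form.

Breath-hold states scale all volumes by a global factor (applied as the
cube root to linear dimensions) and shift structures along CC: deep
inspiration compresses the heart (scale < 1) and pulls it caudally.
Subjects differ by multiplicative lognormal jitter on the translation
and contraction amplitudes, drawn from a generator seeded by
(phantom seed, subject index) so a subject's realized motion is
identical across states — a paired design.

Ground truth (:class:`PhantomTruth`) is computed in closed form from the
realized, post-jitter parameters: per-phase analytic volumes and
centroids, peak-to-peak displacement per axis, and volume variation.
A voxel is foreground iff its center lies inside the analytic primitive.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .masks import (
    DEFAULT_AXIS_MAP,
    DIRECTIONS,
    STATES,
    CardioMotionError,
    MaskVolume,
    PhaseSeries,
    series_filename,
    write_mask,
)

_JITTER_CLIP = (0.5, 1.6)   # keeps jittered structures inside the grid
_SIZE_CLIP = (0.85, 1.18)   # size jitter clip, same purpose
_MAX_CONTRACTION = 0.6      # linear scale amplitude cap (volume ratio ~15.6)


class PhantomError(CardioMotionError):
    """Invalid phantom specification or a structure escaping the grid."""


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class Ellipsoid:
    """Solid ellipsoid; center and semi-axes in mm, patient axes (LR, AP, CC)."""

    center_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.semi_axes_mm):
            raise PhantomError(f"ellipsoid semi-axes must be positive: {self.semi_axes_mm}")

    def base_volume_mm3(self) -> float:
        a, b, c = self.semi_axes_mm
        return 4.0 / 3.0 * np.pi * a * b * c

    def extent_mm(self, direction: str) -> float:
        return self.semi_axes_mm[DIRECTIONS.index(direction)]

    def inside(self, coords: Mapping[str, np.ndarray], scale: float,
               offset: Sequence[float]) -> np.ndarray:
        acc = 0.0
        for d, direction in enumerate(DIRECTIONS):
            r = (coords[direction] - self.center_mm[d] - offset[d]) / (scale * self.semi_axes_mm[d])
            acc = acc + r * r
        return acc <= 1.0


@dataclasses.dataclass(frozen=True)
class EllipsoidShell:
    """Ellipsoid shell (myocardium-like): outer ellipsoid minus the
    concentric inner one whose semi-axes are smaller by ``thickness_mm``."""

    center_mm: tuple[float, float, float]
    outer_semi_axes_mm: tuple[float, float, float]
    thickness_mm: float

    def __post_init__(self) -> None:
        if self.thickness_mm <= 0:
            raise PhantomError("shell thickness must be positive")
        if any(s <= self.thickness_mm for s in self.outer_semi_axes_mm):
            raise PhantomError(
                f"shell thickness {self.thickness_mm} not strictly inside outer "
                f"semi-axes {self.outer_semi_axes_mm}"
            )

    @property
    def inner_semi_axes_mm(self) -> tuple[float, float, float]:
        return tuple(s - self.thickness_mm for s in self.outer_semi_axes_mm)  # type: ignore

    def base_volume_mm3(self) -> float:
        o = self.outer_semi_axes_mm
        i = self.inner_semi_axes_mm
        return 4.0 / 3.0 * np.pi * (o[0] * o[1] * o[2] - i[0] * i[1] * i[2])

    def extent_mm(self, direction: str) -> float:
        return self.outer_semi_axes_mm[DIRECTIONS.index(direction)]

    def inside(self, coords, scale, offset):
        outer = Ellipsoid(self.center_mm, self.outer_semi_axes_mm)
        inner = Ellipsoid(self.center_mm, self.inner_semi_axes_mm)
        return outer.inside(coords, scale, offset) & ~inner.inside(coords, scale, offset)


@dataclasses.dataclass(frozen=True)
class Tube:
    """Circular-cross-section tube (coronary-branch-like) aligned with
    one patient axis, with hemispherical end caps (a capsule): all
    points within ``radius_mm`` of the axial segment of half-length
    ``half_length_mm``.  The rounded caps taper smoothly through slice
    planes, avoiding the whole-slice volume jumps a flat-capped cylinder
    shows at coarse slice spacing."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    half_length_mm: float
    axis: str = "CC"
    #: perpendicular offset (mm, LR/AP/CC) of the +axis endpoint — a
    #: slight obliquity, like a real coronary course; it also spreads the
    #: slice-by-slice sampling phase so voxelization error averages out.
    tilt_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.radius_mm <= 0 or self.half_length_mm <= 0:
            raise PhantomError("tube radius and half-length must be positive")
        if self.axis not in DIRECTIONS:
            raise PhantomError(f"tube axis must be one of {DIRECTIONS}")
        if self.tilt_mm[DIRECTIONS.index(self.axis)] != 0:
            raise PhantomError("tilt_mm must be perpendicular to the tube axis")

    def _half_vector(self) -> np.ndarray:
        u = np.asarray(self.tilt_mm, dtype=float)
        u[DIRECTIONS.index(self.axis)] = self.half_length_mm
        return u

    def base_volume_mm3(self) -> float:
        r = self.radius_mm
        h = float(np.linalg.norm(self._half_vector()))
        return np.pi * r**2 * 2.0 * h + 4.0 / 3.0 * np.pi * r**3

    def extent_mm(self, direction: str) -> float:
        u = self._half_vector()
        return abs(float(u[DIRECTIONS.index(direction)])) + self.radius_mm

    def inside(self, coords, scale, offset):
        # squared distance to the scaled axial segment vs scaled radius
        u = scale * self._half_vector()
        uu = float(u @ u)
        deltas = [
            coords[direction] - self.center_mm[d] - offset[d]
            for d, direction in enumerate(DIRECTIONS)
        ]
        t = sum(dd * ud for dd, ud in zip(deltas, u)) / uu
        t = np.clip(t, -1.0, 1.0)
        acc = 0.0
        for dd, ud in zip(deltas, u):
            perp = dd - t * ud
            acc = acc + perp * perp
        return acc <= (scale * self.radius_mm) ** 2


Primitive = Ellipsoid | EllipsoidShell | Tube


# ---------------------------------------------------------------------------
# specification
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class StructureSpec:
    """One phantom structure: its primitive, per-axis translation
    amplitude (mm, peak-to-peak, patient axes LR/AP/CC) and contraction
    amplitude ``a`` — the fractional linear-scale excursion, so the
    per-cycle volume ratio is ``(1 - a)**-3``."""

    name: str
    primitive: Primitive
    translation_amp_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    contraction: float = 0.0

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.translation_amp_mm):
            raise PhantomError(f"{self.name}: translation amplitudes must be >= 0")
        if not 0 <= self.contraction < 1:
            raise PhantomError(f"{self.name}: contraction must be in [0, 1)")


@dataclasses.dataclass(frozen=True)
class StateFactors:
    """Breath-hold-state effect: a global volume scale (applied to
    linear dimensions as its cube root) and a CC offset in mm
    (negative = caudal)."""

    volume_scale: float = 1.0
    cc_offset_mm: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.volume_scale <= 1.2:
            raise PhantomError(f"volume_scale must be in (0, 1.2], got {self.volume_scale}")


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Full generative specification of a phantom cohort."""

    grid_shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float]
    structures: tuple[StructureSpec, ...]
    state_factors: Mapping[str, StateFactors]
    axis_map: tuple[str, str, str] = DEFAULT_AXIS_MAP
    n_phases: int = 20
    #: lognormal sigma of the per-subject multiplicative jitter on
    #: translation and contraction amplitudes
    subject_sigma: float = 0.15
    #: lognormal sigma of the per-subject jitter on structure linear
    #: size (0.08 on linear dimensions ~ 24% volume SD, the order of
    #: inter-subject cardiac volume spread in adult cohorts)
    size_sigma: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_phases < 2:
            raise PhantomError("n_phases must be >= 2")
        if any(s <= 0 for s in self.spacing_mm) or any(n < 1 for n in self.grid_shape):
            raise PhantomError("invalid grid shape or spacing")
        if self.subject_sigma < 0 or self.size_sigma < 0:
            raise PhantomError("jitter sigmas must be >= 0")
        names = [s.name for s in self.structures]
        if len(set(names)) != len(names):
            raise PhantomError("duplicate structure names in spec")

    @property
    def phase_percents(self) -> tuple[int, ...]:
        return tuple(round(100 * t / self.n_phases) for t in range(self.n_phases))


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclasses.dataclass(eq=False)
class StructureTruth:
    """Closed-form per-phase truth of one structure under the realized
    (post-jitter) parameters of one subject/state."""

    volumes_ml: np.ndarray          # (n_phases,)
    centroids_mm: np.ndarray        # (n_phases, 3), columns LR/AP/CC
    displacement_mm: np.ndarray     # (3,) peak-to-peak per axis
    volume_variation_pct: float
    translation_amp_mm: np.ndarray  # (3,) realized
    contraction: float              # realized
    size_factor: float = 1.0        # realized linear size jitter


@dataclasses.dataclass(eq=False)
class PhantomTruth:
    subject_id: str
    state: str
    structures: dict[str, StructureTruth]


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _motion_profile(n_phases: int) -> np.ndarray:
    """(1 - cos(2*pi*t/n)) / 2 for t = 0..n-1: 0 at phase 0, 1 at n/2."""
    t = np.arange(n_phases)
    return (1.0 - np.cos(2.0 * np.pi * t / n_phases)) / 2.0


def _direction_coords(spec: PhantomSpec) -> dict[str, np.ndarray]:
    """Per patient direction, the physical voxel-center coordinates as a
    broadcastable array along the mapped grid axis."""
    probe = MaskVolume(
        np.zeros(spec.grid_shape, dtype=bool) | True,  # content irrelevant
        spec.spacing_mm, spec.axis_map,
    )
    out = {}
    for direction in DIRECTIONS:
        g, coords = probe.direction_coords(direction)
        shape = [1, 1, 1]
        shape[g] = len(coords)
        out[direction] = coords.reshape(shape)
    return out


def _coord_ranges(spec: PhantomSpec) -> dict[str, tuple[float, float]]:
    coords = _direction_coords(spec)
    return {d: (float(c.min()), float(c.max())) for d, c in coords.items()}


def subject_rng(spec: PhantomSpec, subject_index: int) -> np.random.Generator:
    """Deterministic per-subject generator, independent of state."""
    return np.random.default_rng((spec.seed * 1000003 + subject_index) % (2**31 - 1))


def realize_parameters(
    spec: PhantomSpec, subject_index: int
) -> dict[str, tuple[np.ndarray, float, float]]:
    """Draw the subject's realized (translation amplitude, contraction,
    size factor) per structure: multiplicative lognormal jitter, clipped
    to keep structures inside the grid and contraction below the
    physical cap."""
    rng = subject_rng(spec, subject_index)
    out = {}
    for s in spec.structures:
        factors = np.clip(np.exp(spec.subject_sigma * rng.standard_normal(4)), *_JITTER_CLIP)
        size = float(np.clip(np.exp(spec.size_sigma * rng.standard_normal()), *_SIZE_CLIP))
        amp = np.asarray(s.translation_amp_mm) * factors[:3]
        contraction = min(s.contraction * factors[3], _MAX_CONTRACTION)
        out[s.name] = (amp, contraction, size)
    return out


def generate_subject(
    spec: PhantomSpec, subject_index: int, state: str
) -> tuple[dict[str, PhaseSeries], PhantomTruth]:
    """Voxelise all structures of one subject in one breath-hold state
    and return the phase series plus the closed-form truth.

    Subject jitter depends only on (spec.seed, subject_index), so the
    same subject keeps its realized motion across states.
    """
    if state not in spec.state_factors:
        raise PhantomError(f"state {state!r} has no state_factors entry")
    sf = spec.state_factors[state]
    gamma = sf.volume_scale ** (1.0 / 3.0)
    state_offset = np.array([0.0, 0.0, sf.cc_offset_mm])
    profile = _motion_profile(spec.n_phases)
    coords = _direction_coords(spec)
    ranges = _coord_ranges(spec)
    realized = realize_parameters(spec, subject_index)
    subject_id = f"subject{subject_index:02d}"
    percents = spec.phase_percents

    series: dict[str, PhaseSeries] = {}
    truths: dict[str, StructureTruth] = {}
    for s in spec.structures:
        amp, contraction, size = realized[s.name]
        scales = size * gamma * (1.0 - contraction * profile)   # (n,)
        offsets = amp[None, :] * profile[:, None] + state_offset  # (n, 3)
        masks = []
        for t in range(spec.n_phases):
            # fit check before voxelising, naming phase and structure
            for d, direction in enumerate(DIRECTIONS):
                lo, hi = ranges[direction]
                pos = s.primitive.center_mm[d] + offsets[t, d]
                ext = scales[t] * s.primitive.extent_mm(direction)
                if pos - ext < lo - 1e-9 or pos + ext > hi + 1e-9:
                    raise PhantomError(
                        f"structure {s.name!r} escapes the grid along {direction} "
                        f"at phase {percents[t]}% (subject {subject_index}, state {state})"
                    )
            vox = s.primitive.inside(coords, float(scales[t]), offsets[t])
            masks.append(MaskVolume(vox, spec.spacing_mm, spec.axis_map, s.name))
        series[s.name] = PhaseSeries(masks, percents, subject_id, state, s.name)

        volumes = s.primitive.base_volume_mm3() * scales**3 / 1000.0
        centroids = np.asarray(s.primitive.center_mm)[None, :] + offsets
        truths[s.name] = StructureTruth(
            volumes_ml=volumes,
            centroids_mm=centroids,
            displacement_mm=offsets.max(axis=0) - offsets.min(axis=0),
            volume_variation_pct=float(100.0 * (volumes.max() - volumes.min()) / volumes.min()),
            translation_amp_mm=amp,
            contraction=contraction,
            size_factor=size,
        )
    return series, PhantomTruth(subject_id, state, truths)


# ---------------------------------------------------------------------------
# cohorts on disk
# ---------------------------------------------------------------------------

def truth_frames(truths: Sequence[PhantomTruth]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy (summary, per-phase) DataFrames of a list of subject truths."""
    srows, prows = [], []
    for tr in truths:
        for name, st in tr.structures.items():
            srows.append({
                "subject_id": tr.subject_id, "state": tr.state, "structure": name,
                "disp_lr_mm": st.displacement_mm[0],
                "disp_ap_mm": st.displacement_mm[1],
                "disp_cc_mm": st.displacement_mm[2],
                "volume_variation_pct": st.volume_variation_pct,
                "amp_lr_mm": st.translation_amp_mm[0],
                "amp_ap_mm": st.translation_amp_mm[1],
                "amp_cc_mm": st.translation_amp_mm[2],
                "contraction": st.contraction,
                "size_factor": st.size_factor,
            })
            for t, (v, c) in enumerate(zip(st.volumes_ml, st.centroids_mm)):
                prows.append({
                    "subject_id": tr.subject_id, "state": tr.state, "structure": name,
                    "phase_index": t, "volume_ml": v,
                    "centroid_lr_mm": c[0], "centroid_ap_mm": c[1], "centroid_cc_mm": c[2],
                })
    return pd.DataFrame(srows), pd.DataFrame(prows)


def generate_cohort(
    spec: PhantomSpec,
    n_subjects: int,
    states: Sequence[str],
    out_dir: str | Path,
    file_format: str = "fixture",
) -> Path:
    """Write a full phantom cohort to disk: one directory per subject
    holding per-phase mask files in the canonical naming pattern, plus
    machine-readable truth tables and the spec itself.

    Byte-identical for identical (spec, seed); the plain-text mask
    format is the default for exactly that reason.
    """
    if n_subjects < 1:
        raise PhantomError("n_subjects must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = ".msk" if file_format == "fixture" else ".nii"
    truths = []
    for i in range(n_subjects):
        sdir = out_dir / f"subject{i:02d}"
        sdir.mkdir(exist_ok=True)
        for state in states:
            series, truth = generate_subject(spec, i, state)
            truths.append(truth)
            for name, ps in series.items():
                for pct, mask in zip(ps.phase_percents, ps.phases):
                    fname = series_filename(name, state, pct, extension=ext)
                    write_mask(mask, sdir / fname, file_format)
    summary, phases = truth_frames(truths)
    summary.to_csv(out_dir / "truth_summary.csv", index=False, float_format="%.10g")
    phases.to_csv(out_dir / "truth_phases.csv", index=False, float_format="%.10g")
    save_spec(spec, out_dir / "phantom_spec.yaml")
    return out_dir


def read_truth_summary(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path) if str(path).endswith(".csv") else Path(path) / "truth_summary.csv")


# ---------------------------------------------------------------------------
# spec serialization
# ---------------------------------------------------------------------------

_PRIMITIVE_TAGS = {Ellipsoid: "ellipsoid", EllipsoidShell: "shell", Tube: "tube"}


def _primitive_to_dict(p: Primitive) -> dict:
    d = dataclasses.asdict(p)
    d["type"] = _PRIMITIVE_TAGS[type(p)]
    return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}


def _primitive_from_dict(d: Mapping) -> Primitive:
    d = dict(d)
    tag = d.pop("type")
    cls = {v: k for k, v in _PRIMITIVE_TAGS.items()}[tag]
    for key in ("center_mm", "semi_axes_mm", "outer_semi_axes_mm", "tilt_mm"):
        if key in d:
            d[key] = tuple(d[key])
    return cls(**d)


def spec_to_dict(spec: PhantomSpec) -> dict:
    return {
        "grid_shape": list(spec.grid_shape),
        "spacing_mm": list(spec.spacing_mm),
        "axis_map": list(spec.axis_map),
        "n_phases": spec.n_phases,
        "subject_sigma": spec.subject_sigma,
        "seed": spec.seed,
        "structures": [
            {
                "name": s.name,
                "primitive": _primitive_to_dict(s.primitive),
                "translation_amp_mm": list(s.translation_amp_mm),
                "contraction": s.contraction,
            }
            for s in spec.structures
        ],
        "state_factors": {
            k: {"volume_scale": v.volume_scale, "cc_offset_mm": v.cc_offset_mm}
            for k, v in spec.state_factors.items()
        },
    }


def spec_from_dict(d: Mapping) -> PhantomSpec:
    return PhantomSpec(
        grid_shape=tuple(d["grid_shape"]),
        spacing_mm=tuple(d["spacing_mm"]),
        axis_map=tuple(d.get("axis_map", DEFAULT_AXIS_MAP)),
        n_phases=int(d.get("n_phases", 20)),
        subject_sigma=float(d.get("subject_sigma", 0.15)),
        seed=int(d.get("seed", 0)),
        structures=tuple(
            StructureSpec(
                name=s["name"],
                primitive=_primitive_from_dict(s["primitive"]),
                translation_amp_mm=tuple(s.get("translation_amp_mm", (0, 0, 0))),
                contraction=float(s.get("contraction", 0.0)),
            )
            for s in d["structures"]
        ),
        state_factors={
            k: StateFactors(**v) for k, v in d["state_factors"].items()
        },
    )


def save_spec(spec: PhantomSpec, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(spec_to_dict(spec), sort_keys=True))


def load_spec(path: str | Path) -> PhantomSpec:
    return spec_from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# default inventory
# ---------------------------------------------------------------------------

def default_phantom_spec(seed: int = 0, n_phases: int = 20,
                         subject_sigma: float = 0.15) -> PhantomSpec:
    """The default ten-structure phantom.

    Grid: 36 x 70 x 70 voxels at 5 x 2 x 2 mm (axis 0 = CC with 5 mm
    slices, in-plane 2 mm).  Structure sizes and motion amplitudes are
    illustrative magnitudes of a healthy adult heart: the whole heart
    and pericardium move little and contract mildly, the right
    ventricular myocardium has the largest LR excursion, the coronary
    branches the largest CC excursion, and the chambers have large
    volume excursions.  Breath-hold states: end-expiration slightly
    increases volumes; deep inspiration compresses the heart (volume
    scale 0.88) and shifts it 10 mm caudally.
    """
    E, S, T = Ellipsoid, EllipsoidShell, Tube
    structures = (
        StructureSpec("heart", E((70, 70, 88), (55, 50, 48)), (1.9, 1.0, 2.8), 0.053),
        StructureSpec("pericardium", E((70, 70, 88), (57, 52, 50)), (1.2, 0.65, 2.2), 0.041),
        StructureSpec("LV", E((88, 78, 78), (30, 28, 32)), (3.0, 4.6, 3.4), 0.25),
        StructureSpec("LVM", S((88, 78, 78), (31, 29, 33), 5.0), (2.6, 7.1, 4.2), 0.079),
        StructureSpec("RV", E((48, 66, 80), (28, 25, 27)), (8.0, 4.7, 4.7), 0.234),
        StructureSpec("RVM", S((48, 66, 80), (27, 24, 26), 5.0), (11.7, 7.7, 6.0), 0.15),
        StructureSpec("VS", E((70, 74, 80), (9, 24, 33)), (5.5, 4.3, 4.1), 0.056),
        StructureSpec("AS", E((76, 60, 112), (14, 16, 15)), (3.6, 6.4, 6.4), 0.15),
        StructureSpec("pmLAD", T((52, 46, 100), 6.0, 40.0, "CC", (7.0, 5.0, 0.0)),
                      (5.4, 11.5, 11.8), 0.084),
        StructureSpec("pLCX", T((96, 56, 95), 6.0, 38.0, "CC", (-6.0, 7.0, 0.0)),
                      (8.3, 9.4, 14.4), 0.084),
    )
    return PhantomSpec(
        grid_shape=(36, 70, 70),
        spacing_mm=(5.0, 2.0, 2.0),
        structures=structures,
        state_factors={
            "EIBH": StateFactors(1.0, 0.0),
            "EEBH": StateFactors(1.02, 2.0),
            "DIBH": StateFactors(0.88, -10.0),
        },
        n_phases=n_phases,
        subject_sigma=subject_sigma,
        seed=seed,
    )
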