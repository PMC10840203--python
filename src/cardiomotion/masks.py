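"""Binary mask volumes, cardiac phase series, and mask I/O.

A :class:`MaskVolume` is one 3D binary segmentation with voxel spacing in
mm and an ``axis_map`` assigning each grid axis to a signed patient
direction (LR = left-right, +1 toward patient left; AP =
anterior-posterior, +1 toward posterior; CC = cranio-caudal, +1 toward
cranial).  Physical coordinates are voxel-center based and 0-indexed: the
voxel at grid index ``(i, j, k)`` sits at ``(i*s0, j*s1, k*s2)`` mm along
the grid axes, with the axis_map sign applied when reporting a patient
direction.

Two on-disk formats are supported:

* NIfTI-1 (``.nii`` / ``.nii.gz``), spacing and orientation taken from
  the affine (any nonzero voxel is foreground);
* a line-based plain-text dialect (``.msk``), self-describing and
  diff-friendly, used for test fixtures and for byte-reproducible
  synthetic datasets.  Header lines carry shape/spacing/axes, then each
  slice is stored as run-length-encoded rows (runs alternate
  background/foreground, starting with background).
"""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np

DIRECTIONS = ("LR", "AP", "CC")
#: Default patient-axis assignment when a file carries no usable
#: orientation: axis 0 = CC (+cranial), axis 1 = AP (+posterior),
#: axis 2 = LR (+left) — LPS-style axes typical of thoracic MR exports.
DEFAULT_AXIS_MAP = ("+CC", "+AP", "+LR")

#: The ten canonical structures of the analysis.
STRUCTURES = (
    "heart", "pericardium", "LV", "LVM", "RV",
    "RVM", "VS", "AS", "pmLAD", "pLCX",
)
#: Breath-hold states: end-inspiration, end-expiration, deep inspiration.
STATES = ("EIBH", "EEBH", "DIBH")

#: Canonical 20-phase cardiac cycle, 0–95% in 5% steps.
CANONICAL_PHASES = tuple(range(0, 100, 5))

DEFAULT_NAMING = "{structure}_{state}_phase{percent:03d}"

_FIXTURE_MAGIC = "maskvolume v1"


class CardioMotionError(Exception):
    """Base class for all package errors."""


class MaskIOError(CardioMotionError):
    """File unreadable, unwritable, or not in the expected format."""


class MetadataError(CardioMotionError):
    """Invalid spacing, orientation, or dimensionality metadata."""


class GeometryError(CardioMotionError):
    """Grids that were required to match do not match."""


class SeriesError(CardioMotionError):
    """A phase series violates its invariants (missing reference phase,
    empty phase mask, unordered phases, ...)."""


def _parse_axis_label(label: str) -> tuple[int, str]:
    m = re.fullmatch(r"([+-])(LR|AP|CC)", label)
    if m is None:
        raise MetadataError(f"bad axis label {label!r}; expected e.g. '+CC'")
    return (1 if m.group(1) == "+" else -1), m.group(2)


def _validate_axis_map(axis_map: Sequence[str]) -> tuple[str, str, str]:
    if len(axis_map) != 3:
        raise MetadataError(f"axis_map needs 3 entries, got {len(axis_map)}")
    dirs = [_parse_axis_label(a)[1] for a in axis_map]
    if sorted(dirs) != sorted(DIRECTIONS):
        raise MetadataError(
            f"axis_map {tuple(axis_map)} is not a bijection onto {DIRECTIONS}"
        )
    return tuple(axis_map)  # type: ignore[return-value]


@dataclasses.dataclass(eq=False)
class MaskVolume:
    """One binary 3D mask plus the metadata needed for physical geometry.

    Parameters
    ----------
    voxels
        3D boolean array (any dtype is coerced: nonzero = foreground).
    spacing_mm
        Voxel edge lengths in mm per grid axis; all > 0.
    axis_map
        Signed patient direction per grid axis, e.g. ``("+CC", "+AP",
        "+LR")``; must cover LR/AP/CC exactly once.
    structure_name
        Free label, canonically one of :data:`STRUCTURES`.
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    axis_map: tuple[str, str, str] = DEFAULT_AXIS_MAP
    structure_name: str = ""

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise MetadataError(f"mask must be 3D, got shape {vox.shape}")
        if min(vox.shape) < 1:
            raise MetadataError(f"mask has a zero-length axis: {vox.shape}")
        self.voxels = vox.astype(bool, copy=False)
        spacing = tuple(float(s) for s in self.spacing_mm)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise MetadataError(f"spacing must be 3 positive lengths, got {self.spacing_mm}")
        self.spacing_mm = spacing
        self.axis_map = _validate_axis_map(self.axis_map)

    # -- geometry helpers -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        s = self.spacing_mm
        return s[0] * s[1] * s[2]

    @property
    def n_foreground(self) -> int:
        return int(self.voxels.sum())

    def is_empty(self) -> bool:
        return not self.voxels.any()

    def grid_axis_of(self, direction: str) -> tuple[int, int]:
        """Return ``(grid_axis, sign)`` for a patient direction."""
        for g, label in enumerate(self.axis_map):
            sign, d = _parse_axis_label(label)
            if d == direction:
                return g, sign
        raise MetadataError(f"direction {direction!r} not in axis_map")

    def direction_coords(self, direction: str) -> tuple[int, np.ndarray]:
        """1D physical coordinates (mm) along the grid axis mapped to
        ``direction``, with the axis_map sign applied."""
        g, sign = self.grid_axis_of(direction)
        return g, sign * self.spacing_mm[g] * np.arange(self.shape[g], dtype=float)

    def same_grid(self, other: "MaskVolume") -> bool:
        return (
            self.shape == other.shape
            and self.spacing_mm == other.spacing_mm
            and self.axis_map == other.axis_map
        )

    def equals(self, other: "MaskVolume") -> bool:
        return (
            self.same_grid(other)
            and self.structure_name == other.structure_name
            and bool(np.array_equal(self.voxels, other.voxels))
        )


@dataclasses.dataclass(eq=False)
class PhaseSeries:
    """The per-phase masks of one structure, subject, and breath-hold
    state over the cardiac cycle.  Phase 0% is the reference phase."""

    phases: list[MaskVolume]
    phase_percents: tuple[int, ...]
    subject_id: str
    state: str
    structure_name: str

    def __post_init__(self) -> None:
        self.phase_percents = tuple(int(p) for p in self.phase_percents)
        if len(self.phases) != len(self.phase_percents):
            raise SeriesError("phases and phase_percents differ in length")
        if len(self.phases) < 2:
            raise SeriesError("a phase series needs at least 2 phases")
        if any(b <= a for a, b in zip(self.phase_percents, self.phase_percents[1:])):
            raise SeriesError(f"phase percents not strictly increasing: {self.phase_percents}")
        if self.phase_percents[0] != 0:
            raise SeriesError(
                f"missing reference phase: series starts at {self.phase_percents[0]}%, not 0%"
            )
        ref = self.phases[0]
        for pct, mask in zip(self.phase_percents, self.phases):
            if not mask.same_grid(ref):
                raise GeometryError(
                    f"phase {pct}% grid {mask.shape}/{mask.spacing_mm} does not match "
                    f"reference {ref.shape}/{ref.spacing_mm}"
                )
            if mask.is_empty():
                raise SeriesError(f"phase {pct}% mask of {self.structure_name!r} is empty")

    @property
    def n_phases(self) -> int:
        return len(self.phases)


# ---------------------------------------------------------------------------
# fixture (plain-text) dialect
# ---------------------------------------------------------------------------

def _fmt_float(x: float) -> str:
    return format(float(x), ".10g")


def _rle_encode_row(row: np.ndarray) -> str:
    # runs alternate background/foreground, starting with background
    runs: list[int] = []
    current = False
    count = 0
    for v in row:
        v = bool(v)
        if v == current:
            count += 1
        else:
            runs.append(count)
            current = v
            count = 1
    runs.append(count)
    return " ".join(str(r) for r in runs)


def _rle_decode_row(text: str, width: int, where: str) -> np.ndarray:
    try:
        runs = [int(t) for t in text.split()]
    except ValueError as exc:
        raise MaskIOError(f"bad run-length row in {where}: {text!r}") from exc
    if sum(runs) != width or any(r < 0 for r in runs):
        raise MaskIOError(
            f"run lengths {runs} do not sum to row width {width} in {where}"
        )
    row = np.zeros(width, dtype=bool)
    pos = 0
    fg = False
    for r in runs:
        if fg:
            row[pos:pos + r] = True
        pos += r
        fg = not fg
    return row


def _write_fixture(mask: MaskVolume, path: Path) -> None:
    lines = [
        _FIXTURE_MAGIC,
        f"structure {mask.structure_name}",
        "shape " + " ".join(str(n) for n in mask.shape),
        "spacing_mm " + " ".join(_fmt_float(s) for s in mask.spacing_mm),
        "axes " + " ".join(mask.axis_map),
    ]
    for i in range(mask.shape[0]):
        lines.append(f"slice {i}")
        for j in range(mask.shape[1]):
            lines.append(_rle_encode_row(mask.voxels[i, j]))
    path.write_text("\n".join(lines) + "\n")


def _read_fixture(path: Path) -> MaskVolume:
    lines = path.read_text().splitlines()
    if not lines or lines[0] != _FIXTURE_MAGIC:
        raise MaskIOError(f"{path}: not a '{_FIXTURE_MAGIC}' file")
    try:
        structure = lines[1].split(" ", 1)[1] if " " in lines[1] else ""
        shape = tuple(int(t) for t in lines[2].split()[1:])
        spacing = tuple(float(t) for t in lines[3].split()[1:])
        axes = tuple(lines[4].split()[1:])
    except (IndexError, ValueError) as exc:
        raise MaskIOError(f"{path}: malformed fixture header") from exc
    if len(shape) != 3:
        raise MetadataError(f"{path}: fixture payload must be 3D, got shape {shape}")
    vox = np.zeros(shape, dtype=bool)
    cursor = 5
    for i in range(shape[0]):
        if cursor >= len(lines) or lines[cursor] != f"slice {i}":
            raise MaskIOError(f"{path}: expected 'slice {i}' at line {cursor + 1}")
        cursor += 1
        for j in range(shape[1]):
            if cursor >= len(lines):
                raise MaskIOError(f"{path}: truncated at slice {i}, row {j}")
            vox[i, j] = _rle_decode_row(lines[cursor], shape[2], f"{path} slice {i} row {j}")
            cursor += 1
    return MaskVolume(vox, spacing, axes, structure)  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------

# unit world-direction (RAS+) per signed patient label: +LR is toward
# patient left = -x, +AP toward posterior = -y, +CC toward cranial = +z
_DIR_VEC = {
    "+LR": (-1.0, 0.0, 0.0), "-LR": (1.0, 0.0, 0.0),
    "+AP": (0.0, -1.0, 0.0), "-AP": (0.0, 1.0, 0.0),
    "+CC": (0.0, 0.0, 1.0), "-CC": (0.0, 0.0, -1.0),
}
_VEC_DIR = {("x", -1): "+LR", ("x", 1): "-LR",
            ("y", -1): "+AP", ("y", 1): "-AP",
            ("z", 1): "+CC", ("z", -1): "-CC"}


def _affine_from(mask: MaskVolume) -> np.ndarray:
    aff = np.eye(4)
    for g, label in enumerate(mask.axis_map):
        aff[:3, g] = np.asarray(_DIR_VEC[label]) * mask.spacing_mm[g]
    return aff


def _axis_map_from_affine(aff: np.ndarray, default: Sequence[str]) -> tuple[tuple[str, ...], tuple[float, ...] | None]:
    """Derive (axis_map, spacing) from a NIfTI affine; fall back to the
    configured default map (and header zooms) for an identity affine."""
    if np.allclose(aff, np.eye(4)):
        return tuple(default), None
    labels = []
    spacing = []
    for g in range(3):
        col = aff[:3, g]
        norm = float(np.linalg.norm(col))
        if norm <= 0:
            raise MetadataError("affine column has zero length")
        w = int(np.argmax(np.abs(col)))
        sign = 1 if col[w] > 0 else -1
        labels.append(_VEC_DIR[("xyz"[w], sign)])
        spacing.append(norm)
    _validate_axis_map(labels)
    return tuple(labels), tuple(spacing)


def _read_nifti(path: Path, default_axis_map: Sequence[str]) -> MaskVolume:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types
        raise MaskIOError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise MetadataError(f"{path}: expected a 3D volume, got {data.ndim}D payload")
    axis_map, aff_spacing = _axis_map_from_affine(img.affine, default_axis_map)
    if aff_spacing is None:
        zooms = img.header.get_zooms()[:3]
        spacing = tuple(float(z) for z in zooms)
    else:
        spacing = aff_spacing
    if any(s <= 0 for s in spacing):
        raise MetadataError(f"{path}: nonpositive voxel spacing {spacing}")
    return MaskVolume(data != 0, spacing, axis_map)  # type: ignore[arg-type]


def _write_nifti(mask: MaskVolume, path: Path) -> None:
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), _affine_from(mask))
    img.header.set_zooms(mask.spacing_mm)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# public I/O
# ---------------------------------------------------------------------------

def _infer_format(path: Path, file_format: str | None) -> str:
    if file_format is not None:
        if file_format not in ("nifti", "fixture"):
            raise MaskIOError(f"unknown format {file_format!r}")
        return file_format
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    return "fixture"


def read_mask(
    path: str | Path,
    file_format: str | None = None,
    structure_name: str | None = None,
    default_axis_map: Sequence[str] = DEFAULT_AXIS_MAP,
) -> MaskVolume:
    """Read one mask volume.

    ``file_format`` is ``"nifti"``, ``"fixture"``, or None to infer from
    the extension.  For NIfTI, spacing and orientation come from the
    affine; an identity affine falls back to ``default_axis_map``.
    """
    path = Path(path)
    if not path.exists():
        raise MaskIOError(f"mask file does not exist: {path}")
    fmt = _infer_format(path, file_format)
    mask = _read_nifti(path, default_axis_map) if fmt == "nifti" else _read_fixture(path)
    if structure_name is not None:
        mask.structure_name = structure_name
    return mask


def write_mask(mask: MaskVolume, path: str | Path, file_format: str | None = None) -> None:
    """Write a mask so that :func:`read_mask` reproduces it exactly.

    Writing an empty mask is permitted (and round-trips); assembling an
    empty mask into a :class:`PhaseSeries` is what fails.
    """
    path = Path(path)
    if not path.parent.is_dir():
        raise MaskIOError(f"parent directory does not exist: {path.parent}")
    fmt = _infer_format(path, file_format)
    if fmt == "nifti":
        _write_nifti(mask, path)
    else:
        _write_fixture(mask, path)


def read_labelmap(
    path: str | Path,
    label_table: dict[int, str],
    default_axis_map: Sequence[str] = DEFAULT_AXIS_MAP,
) -> dict[str, MaskVolume]:
    """Split a multi-label NIfTI volume into per-structure binary masks.

    ``label_table`` maps integer voxel values to structure names; labels
    not in the table are ignored.  For binary-per-structure exports use
    :func:`read_mask` instead (any nonzero value is foreground there).
    """
    path = Path(path)
    if not path.exists():
        raise MaskIOError(f"label map does not exist: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise MaskIOError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise MetadataError(f"{path}: expected a 3D label map, got {data.ndim}D")
    template = _read_nifti(path, default_axis_map)
    out = {}
    for label, structure in sorted(label_table.items()):
        out[structure] = MaskVolume(
            data == label, template.spacing_mm, template.axis_map, structure
        )
    return out


def _pattern_to_regex(pattern: str) -> re.Pattern[str]:
    out = []
    pos = 0
    for m in re.finditer(r"\{(structure|state|percent:03d|percent)\}", pattern):
        out.append(re.escape(pattern[pos:m.start()]))
        field = m.group(1)
        if field.startswith("percent"):
            out.append(r"(?P<percent>\d+)")
        else:
            out.append(rf"(?P<{field}>[^_/]+)")
        pos = m.end()
    out.append(re.escape(pattern[pos:]))
    return re.compile("".join(out) + r"\.(msk|txt|nii|nii\.gz)$")


def series_filename(
    structure: str, state: str, percent: int,
    pattern: str = DEFAULT_NAMING, extension: str = ".msk",
) -> str:
    return pattern.format(structure=structure, state=state, percent=percent) + extension


def load_series(
    directory: str | Path,
    structure: str,
    state: str,
    subject_id: str = "",
    pattern: str = DEFAULT_NAMING,
    file_format: str | None = None,
    default_axis_map: Sequence[str] = DEFAULT_AXIS_MAP,
) -> PhaseSeries:
    """Assemble the per-phase mask files of one (structure, state) from a
    directory into a :class:`PhaseSeries`, sorted by phase percent.

    Filenames must follow ``pattern`` (default
    ``"{structure}_{state}_phase{percent:03d}"``) with a recognised mask
    extension.  The result is independent of directory listing order, and
    all series invariants (0% reference present, matching grids,
    non-empty phases) are enforced.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise MaskIOError(f"not a directory: {directory}")
    rx = _pattern_to_regex(pattern)
    found: dict[int, Path] = {}
    for p in sorted(directory.iterdir()):
        m = rx.fullmatch(p.name)
        if not m:
            continue
        g = m.groupdict()
        if g.get("structure", structure) != structure or g.get("state", state) != state:
            continue
        pct = int(g["percent"])
        if pct in found:
            raise MaskIOError(f"duplicate files for phase {pct}% in {directory}")
        found[pct] = p
    if not found:
        raise MaskIOError(
            f"no phase files for structure={structure!r} state={state!r} in {directory}"
        )
    percents = sorted(found)
    if percents[0] != 0:
        raise SeriesError(
            f"missing reference phase: no 0% file for {structure}/{state} in {directory}"
        )
    masks = [
        read_mask(found[p], file_format, structure_name=structure,
                  default_axis_map=default_axis_map)
        for p in percents
    ]
    return PhaseSeries(masks, tuple(percents), subject_id, state, structure)


def assemble_series(
    masks: Iterable[MaskVolume],
    phase_percents: Iterable[int],
    subject_id: str,
    state: str,
    structure_name: str,
) -> PhaseSeries:
    """Build a validated :class:`PhaseSeries` from in-memory masks."""
    return PhaseSeries(list(masks), tuple(phase_percents), subject_id, state, structure_name)
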