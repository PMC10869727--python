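"""Core cohort types and I/O for tomogram-based survival analysis.

This module holds the shared vocabulary of the package: right-censored
follow-up records (:class:`SubjectOutcome`), multi-slice grayscale perfusion
studies (:class:`TomogramStudy`), risk scores, clinical covariates, and the
train/test + k-fold cohort split used by the trainer.  It also owns the plain
CSV/PNG/array-container dialects every other module reads and writes.

A study is a stack of equal-sized 2D slices acquired under two physiologic
conditions (rest, pharmacologic/exercise stress) and re-sliced along three
cardiac axes (short, horizontal long, vertical long).  The clinically
standard layout is 96 slices: per condition, 24 short-axis + 12 horizontal
long-axis + 12 vertical long-axis slices.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image

CONDITIONS = ("rest", "stress")
AXES = ("short", "horizontal_long", "vertical_long")

#: slices per axis in the standard acquisition layout (per condition)
PAPER_AXIS_COUNTS = {"short": 24, "horizontal_long": 12, "vertical_long": 12}
#: desk-scale layout used for fast simulation profiles (per condition)
REDUCED_AXIS_COUNTS = {"short": 2, "horizontal_long": 1, "vertical_long": 1}

SURVIVAL_COLUMNS = ("subject_id", "time_days", "event")
MANIFEST_COLUMNS = ("subject_id", "file", "condition", "axis", "slice_index")
CLINICAL_COLUMNS = (
    "subject_id", "age", "sex", "diabetes", "hypertension",
    "hyperlipidemia", "smoking",
)

LayoutEntry = tuple[str, str, int]


def layout_entries(axis_counts: Mapping[str, int]) -> tuple[LayoutEntry, ...]:
    """Canonically ordered layout tuples for the given per-axis slice counts."""
    entries: list[LayoutEntry] = []
    for cond in CONDITIONS:
        for axis in AXES:
            for i in range(axis_counts[axis]):
                entries.append((cond, axis, i))
    return tuple(entries)


def paper_layout() -> tuple[LayoutEntry, ...]:
    """The 96-slice standard layout: 2 conditions x (24 + 12 + 12) slices."""
    return layout_entries(PAPER_AXIS_COUNTS)


def reduced_layout() -> tuple[LayoutEntry, ...]:
    """An 8-slice desk-scale layout: 2 conditions x (2 + 1 + 1) slices."""
    return layout_entries(REDUCED_AXIS_COUNTS)


def _layout_key(entry: LayoutEntry) -> tuple[int, int, int]:
    cond, axis, idx = entry
    return (CONDITIONS.index(cond), AXES.index(axis), int(idx))


@dataclass(frozen=True)
class SubjectOutcome:
    """One subject's right-censored follow-up: time t_i (days) and event flag."""

    subject_id: str
    time_days: float
    event: int

    def __post_init__(self) -> None:
        if not (self.time_days > 0 and math.isfinite(self.time_days)):
            raise ValueError(
                f"non-positive follow-up time for subject {self.subject_id!r}: "
                f"{self.time_days}"
            )
        if self.event not in (0, 1):
            raise ValueError(
                f"event indicator must be 0 or 1, got {self.event!r} "
                f"for subject {self.subject_id!r}"
            )


@dataclass(frozen=True)
class RiskScore:
    """A scalar log-relative-hazard f(x_i) emitted by a scorer."""

    subject_id: str
    score: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.score):
            raise ValueError(f"non-finite score for subject {self.subject_id!r}")


@dataclass(frozen=True)
class ClinicalCovariates:
    """Baseline clinical variables used by the fusion network variants."""

    subject_id: str
    age: float
    sex: int
    diabetes: int
    hypertension: int
    hyperlipidemia: int
    smoking: int

    def as_vector(self) -> np.ndarray:
        return np.array(
            [self.age, self.sex, self.diabetes, self.hypertension,
             self.hyperlipidemia, self.smoking],
            dtype=np.float64,
        )


@dataclass
class TomogramStudy:
    """A per-subject stack of grayscale slices with condition/axis layout.

    ``slices`` is an (n_slices, height, width) float array with values in
    [0, 1] after per-study min-max normalization; ``layout[k]`` names slice k
    as (condition, axis, within-axis index).  Slices are stored in canonical
    order: rest before stress, axes in (short, horizontal_long,
    vertical_long) order, ascending index.
    """

    subject_id: str
    slices: np.ndarray
    layout: tuple[LayoutEntry, ...]

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices, dtype=np.float64)
        if self.slices.ndim != 3:
            raise ValueError("slices must be a (n, h, w) array")
        if len(self.layout) != self.slices.shape[0]:
            raise ValueError("layout length must match slice count")
        self.layout = tuple((c, a, int(i)) for c, a, i in self.layout)
        for cond, axis, _ in self.layout:
            if cond not in CONDITIONS or axis not in AXES:
                raise ValueError(f"unknown layout entry ({cond}, {axis})")
        if len(set(self.layout)) != len(self.layout):
            raise ValueError("layout entries must be unique")
        keys = [_layout_key(e) for e in self.layout]
        if keys != sorted(keys):
            order = np.argsort(
                np.array([k[0] * 10**6 + k[1] * 10**3 + k[2] for k in keys])
            )
            self.slices = self.slices[order]
            self.layout = tuple(self.layout[i] for i in order)

    @property
    def n_slices(self) -> int:
        return int(self.slices.shape[0])

    @property
    def slice_shape(self) -> tuple[int, int]:
        return (int(self.slices.shape[1]), int(self.slices.shape[2]))

    def validate_paper_layout(self) -> None:
        """Raise unless the study carries the full 96-slice standard layout."""
        if self.layout != paper_layout():
            raise ValueError(
                f"non-conformant layout: expected the 96-slice standard stack, "
                f"got {self.n_slices} slices"
            )

    def condition_axis_slices(self, condition: str, axis: str) -> np.ndarray:
        idx = [k for k, (c, a, _) in enumerate(self.layout)
               if c == condition and a == axis]
        return self.slices[idx]


@dataclass(frozen=True)
class CohortSplit:
    """Disjoint assignment of subjects to the held-out test set or a CV fold.

    ``fold_assignments`` maps subject_id to either the string ``"test"`` or a
    training fold number in 1..k.
    """

    fold_assignments: Mapping[str, object]
    k_folds: int

    def subjects(self, role: object) -> list[str]:
        return sorted(s for s, r in self.fold_assignments.items() if r == role)

    @property
    def test_subjects(self) -> list[str]:
        return self.subjects("test")

    @property
    def train_subjects(self) -> list[str]:
        return sorted(
            s for s, r in self.fold_assignments.items() if r != "test"
        )


# ---------------------------------------------------------------------------
# survival / clinical table I/O
# ---------------------------------------------------------------------------

def read_survival_table(path: str | Path) -> list[SubjectOutcome]:
    """Read a `subject_id,time_days,event` CSV into outcome records.

    Raises ``ValueError`` on missing columns, duplicated subject ids,
    non-positive follow-up times, or event flags outside {0, 1}.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in SURVIVAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"survival table missing column(s): {missing}")
    ids = df["subject_id"].astype(str)
    dup = ids[ids.duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate subject id(s): {sorted(set(dup))}")
    out = []
    for _, row in df.iterrows():
        out.append(
            SubjectOutcome(str(row["subject_id"]), float(row["time_days"]),
                           int(row["event"]))
        )
    return out


def write_survival_table(outcomes: Iterable[SubjectOutcome],
                         path: str | Path) -> None:
    df = pd.DataFrame(
        [(o.subject_id, o.time_days, o.event) for o in outcomes],
        columns=list(SURVIVAL_COLUMNS),
    )
    df.to_csv(path, index=False)


def read_clinical_table(path: str | Path) -> dict[str, ClinicalCovariates]:
    """Read the clinical covariate CSV; rows with any missing value are rejected."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table missing column(s): {missing}")
    if df[list(CLINICAL_COLUMNS)].isna().any().any():
        bad = df.index[df[list(CLINICAL_COLUMNS)].isna().any(axis=1)].tolist()
        raise ValueError(f"clinical table has missing values in rows {bad}")
    out: dict[str, ClinicalCovariates] = {}
    for _, row in df.iterrows():
        sid = str(row["subject_id"])
        if sid in out:
            raise ValueError(f"duplicate subject id(s): [{sid!r}]")
        out[sid] = ClinicalCovariates(
            sid, float(row["age"]), int(row["sex"]), int(row["diabetes"]),
            int(row["hypertension"]), int(row["hyperlipidemia"]),
            int(row["smoking"]),
        )
    return out


# ---------------------------------------------------------------------------
# tomogram I/O
# ---------------------------------------------------------------------------

def minmax_normalize(stack: np.ndarray) -> np.ndarray:
    """Per-study min-max rescale to [0, 1]; constant stacks map to all zeros."""
    stack = np.asarray(stack, dtype=np.float64)
    lo, hi = float(stack.min()), float(stack.max())
    if hi - lo <= 0:
        warnings.warn(
            "constant-intensity study: zero dynamic range, mapping to zeros",
            stacklevel=2,
        )
        return np.zeros_like(stack)
    return (stack - lo) / (hi - lo)


def _read_gray_image(path: Path) -> np.ndarray:
    with Image.open(path) as im:
        if im.mode not in ("L", "I", "I;16", "F"):
            im = im.convert("I")
        arr = np.asarray(im, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"{path} is not a single-channel grayscale image")
    return arr


def load_tomogram_study(manifest_rows: pd.DataFrame,
                        base_dir: str | Path = ".",
                        strict: bool = False) -> TomogramStudy:
    """Assemble one subject's study from its manifest rows.

    ``manifest_rows`` must carry the manifest CSV columns for a single
    subject.  Slice image files are read relative to ``base_dir``; a manifest
    whose ``file`` column points at a ``.npz`` array container is loaded
    through :func:`load_study_container` instead.  Intensities are min-max
    rescaled per study.  With ``strict=True`` the 96-slice standard layout is
    enforced.
    """
    rows = manifest_rows
    missing = [c for c in MANIFEST_COLUMNS if c not in rows.columns]
    if missing:
        raise ValueError(f"manifest missing column(s): {missing}")
    sids = set(rows["subject_id"].astype(str))
    if len(sids) != 1:
        raise ValueError("manifest rows must belong to a single subject")
    sid = sids.pop()
    base = Path(base_dir)

    files = set(rows["file"].astype(str))
    if len(files) == 1 and next(iter(files)).endswith(".npz"):
        study = load_study_container(base / next(iter(files)))
        if study.subject_id != sid:
            raise ValueError("container subject id disagrees with manifest")
        if strict:
            study.validate_paper_layout()
        return study

    entries: list[tuple[LayoutEntry, np.ndarray]] = []
    for _, row in rows.iterrows():
        entry = (str(row["condition"]), str(row["axis"]),
                 int(row["slice_index"]))
        entries.append((entry, _read_gray_image(base / str(row["file"]))))
    entries.sort(key=lambda it: _layout_key(it[0]))
    shapes = {a.shape for _, a in entries}
    if len(shapes) != 1:
        raise ValueError(f"mismatched slice dimensions for {sid!r}: {shapes}")
    stack = minmax_normalize(np.stack([a for _, a in entries]))
    study = TomogramStudy(sid, stack, tuple(e for e, _ in entries))
    if strict:
        study.validate_paper_layout()
    return study


def load_cohort_studies(manifest_path: str | Path,
                        base_dir: str | Path | None = None,
                        strict: bool = False) -> dict[str, TomogramStudy]:
    """Load every subject referenced by a manifest CSV."""
    manifest_path = Path(manifest_path)
    base = Path(base_dir) if base_dir is not None else manifest_path.parent
    df = pd.read_csv(manifest_path)
    out = {}
    for sid, rows in df.groupby(df["subject_id"].astype(str), sort=True):
        out[str(sid)] = load_tomogram_study(rows, base, strict=strict)
    return out


def save_study_container(study: TomogramStudy, path: str | Path) -> None:
    """Write a study as a single compressed array container (.npz).

    Stores the float slice stack plus a JSON layout block, so the container
    round-trips to the identical :class:`TomogramStudy` as the per-slice PNG
    dialect.
    """
    import json

    np.savez_compressed(
        path,
        slices=study.slices.astype(np.float32),
        meta=np.array(
            json.dumps({"subject_id": study.subject_id,
                        "layout": [list(e) for e in study.layout]})
        ),
    )


def load_study_container(path: str | Path) -> TomogramStudy:
    import json

    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        stack = np.asarray(z["slices"], dtype=np.float64)
    layout = tuple((c, a, int(i)) for c, a, i in meta["layout"])
    return TomogramStudy(meta["subject_id"], minmax_normalize(stack), layout)


# ---------------------------------------------------------------------------
# cohort splitting
# ---------------------------------------------------------------------------

def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def split_cohort(subject_ids: Sequence[str], test_fraction: float,
                 k_folds: int, seed: int) -> CohortSplit:
    """Randomly reserve a test set and partition the rest into k CV folds.

    The test set has ``round(n * test_fraction)`` subjects (half away from
    zero); the remaining subjects are split into ``k_folds`` folds whose
    sizes differ by at most one.  Deterministic for a given seed; roles are
    disjoint and exhaustive.
    """
    ids = [str(s) for s in subject_ids]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject id(s) in cohort")
    if not (0.0 < test_fraction < 1.0):
        raise ValueError("test_fraction must lie in (0, 1)")
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    n = len(ids)
    if n < k_folds + 1:
        raise ValueError(f"too few subjects ({n}) for {k_folds}-fold splitting")
    n_test = _round_half_away(n * test_fraction)
    n_test = min(max(n_test, 0), n - k_folds)  # leave >=1 subject per fold

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    assignment: dict[str, object] = {}
    for pos in order[:n_test]:
        assignment[ids[pos]] = "test"
    train_positions = order[n_test:]
    for fold, chunk in enumerate(np.array_split(train_positions, k_folds), 1):
        for pos in chunk:
            assignment[ids[pos]] = fold
    return CohortSplit(assignment, k_folds)


def align_outcomes(outcomes: Iterable[SubjectOutcome],
                   subject_ids: Sequence[str]) -> list[SubjectOutcome]:
    """Reorder outcome records to a given subject-id sequence."""
    by_id = {o.subject_id: o for o in outcomes}
    missing = [s for s in subject_ids if s not in by_id]
    if missing:
        raise ValueError(f"no outcome record for subject(s): {missing[:5]}")
    return [by_id[s] for s in subject_ids]
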