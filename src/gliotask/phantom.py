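"""Synthetic multimodal glioma phantoms with planted, tunable class signals.

Each cohort contains four modality volumes (T1, T1CE, T2, FLAIR) per subject,
a 3-compartment tumor mask (necrotic core / enhancing rim / edema), binary
IDH and grade labels, and a 101-wide tabular feature vector. Two signals are
planted so that every downstream stage is testable without real data:

* IDH-mutant subjects receive tumor-interior T2 hyperintensity with matched
  FLAIR suppression (a synthetic T2-FLAIR mismatch), scaled by
  ``mismatch_effect``;
* high-grade subjects receive an inflated necrotic core, scaled by
  ``necrosis_effect``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

MODALITIES = ("t1", "t1ce", "t2", "flair")

# compartment labels in roi_mask
BACKGROUND, NECROTIC, ENHANCING, EDEMA = 0, 1, 2, 3

_MIN_GRID = 12

# additive intensity offsets per (compartment, modality), arbitrary units.
# T2 and FLAIR offsets are kept identical so that, by construction, the only
# IDH-dependent difference between them is the planted mismatch signal.
_OFFSETS = {
    EDEMA: {"t1": -0.2, "t1ce": 0.0, "t2": 0.8, "flair": 0.8},
    ENHANCING: {"t1": 0.0, "t1ce": 1.0, "t2": 0.5, "flair": 0.5},
    NECROTIC: {"t1": -0.4, "t1ce": -0.5, "t2": 0.7, "flair": 0.7},
}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic cohort; identical spec + seed => identical data."""

    n_subjects: int = 20
    grid_size: int = 32
    idh_mutant_fraction: float = 0.5
    high_grade_fraction: float = 0.5
    mismatch_effect: float = 1.0
    necrosis_effect: float = 1.0
    noise_sd: float = 0.1
    seed: int = 0
    label_coupling: float = 0.5
    n_informative: int = 10
    feature_effect: float = 1.5

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError(f"n_subjects must be >= 2, got {self.n_subjects}")
        if self.grid_size < _MIN_GRID:
            raise ValueError(
                f"grid_size {self.grid_size} too small to contain a tumor "
                f"(minimum {_MIN_GRID})")
        for name in ("idh_mutant_fraction", "high_grade_fraction", "label_coupling"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("mismatch_effect", "necrosis_effect", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class PhantomSubject:
    """One synthetic patient: 4 modality volumes, mask, labels, tabular features."""

    subject_id: str
    volumes: dict[str, np.ndarray]
    roi_mask: np.ndarray
    idh_label: int
    grade_label: int
    features: np.ndarray = field(default_factory=lambda: np.zeros(101))

    def stacked(self) -> np.ndarray:
        """(4, D, H, W) array in MODALITIES order."""
        return np.stack([self.volumes[m] for m in MODALITIES])


@dataclass
class FeatureTableResult:
    table: pd.DataFrame
    idh_labels: np.ndarray
    grade_labels: np.ndarray
    informative_idh: list[int]
    informative_grade: list[int]


def _joint_label_counts(n: int, p_mut: float, p_high: float,
                        coupling: float) -> tuple[int, int, int, int]:
    """Cell counts (mut&high, mut&low, wt&high, wt&low) with exact marginals.

    ``coupling`` interpolates between independence (0) and the maximal
    negative association of mutant with high grade (1), reflecting that IDH
    wildtype co-occurs with high grade.
    """
    n_mut = round(n * p_mut)
    n_high = round(n * p_high)
    mh_min = max(0, n_mut + n_high - n)
    mh_ind = n_mut * n_high / n
    mh = int(round((1 - coupling) * mh_ind + coupling * mh_min))
    mh = min(max(mh, mh_min), min(n_mut, n_high))
    return mh, n_mut - mh, n_high - mh, n - n_mut - n_high + mh


def _ellipsoid_distance(grid: int, center: np.ndarray, radii: np.ndarray) -> np.ndarray:
    coords = np.indices((grid, grid, grid), dtype=np.float64)
    d2 = np.zeros((grid, grid, grid))
    for ax in range(3):
        d2 += ((coords[ax] - center[ax]) / radii[ax]) ** 2
    return d2


def _make_subject(idx: int, spec: PhantomSpec, idh: int, grade: int,
                  rng: np.random.Generator) -> PhantomSubject:
    g = spec.grid_size
    center = rng.uniform(0.38, 0.62, size=3) * g
    radii = rng.uniform(0.20, 0.28, size=3) * g
    d2 = _ellipsoid_distance(g, center, radii)

    enh_scale = 0.65
    core_scale = 0.35 * (1.0 + (0.25 * spec.necrosis_effect if grade else 0.0))
    core_scale = min(core_scale, 0.85 * enh_scale)

    mask = np.zeros((g, g, g), dtype=np.int16)
    mask[d2 <= 1.0] = EDEMA
    enh_region = d2 <= enh_scale ** 2
    mask[enh_region] = ENHANCING
    # keep the core strictly inside the enhancing rim
    core = (d2 <= core_scale ** 2) & ndimage.binary_erosion(enh_region)
    mask[core] = NECROTIC

    volumes = {}
    interior = (mask == NECROTIC) | (mask == ENHANCING)
    for m in MODALITIES:
        vol = np.ones((g, g, g))
        for label, offsets in _OFFSETS.items():
            vol[mask == label] += offsets[m]
        if idh:
            shift = 0.4 * spec.mismatch_effect
            if m == "t2":
                vol[interior] += shift
            elif m == "flair":
                vol[interior] -= shift
        vol += rng.normal(0.0, spec.noise_sd, size=vol.shape)
        # z-score within the (whole-volume) brain mask
        vol = (vol - vol.mean()) / (vol.std() + 1e-12)
        volumes[m] = vol.astype(np.float64)

    return PhantomSubject(
        subject_id=f"sub-{idx:04d}", volumes=volumes, roi_mask=mask,
        idh_label=idh, grade_label=grade)


def generate_cohort(spec: PhantomSpec) -> list[PhantomSubject]:
    """Generate a deterministic, stratified synthetic cohort."""
    n = spec.n_subjects
    mh, ml, wh, wl = _joint_label_counts(
        n, spec.idh_mutant_fraction, spec.high_grade_fraction, spec.label_coupling)
    labels = ([(1, 1)] * mh + [(1, 0)] * ml + [(0, 1)] * wh + [(0, 0)] * wl)

    master = np.random.default_rng(spec.seed)
    order = master.permutation(n)
    labels = [labels[i] for i in order]

    children = np.random.SeedSequence(spec.seed).spawn(n + 1)
    subjects = [
        _make_subject(i, spec, idh, grade, np.random.default_rng(children[i]))
        for i, (idh, grade) in enumerate(labels)
    ]

    feat = make_feature_table(
        subjects, n_informative=spec.n_informative, effect=spec.feature_effect,
        seed=int(children[n].generate_state(1)[0] % (2 ** 31)))
    for subject, row in zip(subjects, feat.table.to_numpy()):
        subject.features = row.astype(np.float64)
    return subjects


def make_feature_table(subjects: list[PhantomSubject], n_informative: int = 10,
                       effect: float = 1.5, seed: int = 0) -> FeatureTableResult:
    """Build a 101-column tabular feature table (99 radiomic-like + age + sex).

    ``n_informative`` of the 99 radiomic-like columns are shifted by
    ``effect`` standard deviations between classes; the planted columns are
    split between the IDH and grade tasks. Age is shifted older for IDH
    wildtype; sex is uninformative.
    """
    if n_informative > 99:
        raise ValueError(f"n_informative must be <= 99, got {n_informative}")
    rng = np.random.default_rng(seed)
    n = len(subjects)
    idh = np.array([s.idh_label for s in subjects], dtype=np.int64)
    grade = np.array([s.grade_label for s in subjects], dtype=np.int64)

    X = rng.normal(size=(n, 99))
    n_idh = (n_informative + 1) // 2
    informative_idh = list(range(n_idh))
    informative_grade = list(range(n_idh, n_informative))
    for j in informative_idh:
        X[:, j] += effect * idh
    for j in informative_grade:
        X[:, j] += effect * grade

    age = 57.0 + 6.0 * (1 - idh) + rng.normal(0.0, 8.0, size=n)
    sex = rng.integers(0, 2, size=n).astype(np.float64)

    cols = [f"radiomic_{j:03d}" for j in range(99)] + ["age", "sex"]
    table = pd.DataFrame(
        np.column_stack([X, age, sex]), columns=cols,
        index=[s.subject_id for s in subjects])
    return FeatureTableResult(table, idh, grade, informative_idh, informative_grade)


def extract_patch(subject: PhantomSubject, patch_size: int) -> PhantomSubject:
    """Crop a cubic patch centered on the ROI bounding-box midpoint.

    Regions outside the volume are zero-padded so the ROI midpoint stays at
    the patch center.
    """
    mask = subject.roi_mask
    if not (mask > 0).any():
        raise ValueError(f"subject {subject.subject_id} has an empty ROI mask")
    p = patch_size
    starts = []
    for ax in range(3):
        idxs = np.where((mask > 0).any(axis=tuple(a for a in range(3) if a != ax)))[0]
        mid = (int(idxs[0]) + int(idxs[-1]) + 1) // 2
        starts.append(mid - p // 2)

    def crop(vol: np.ndarray) -> np.ndarray:
        out = np.zeros((p, p, p), dtype=vol.dtype)
        src, dst = [], []
        for ax, s in enumerate(starts):
            lo, hi = max(s, 0), min(s + p, vol.shape[ax])
            src.append(slice(lo, hi))
            dst.append(slice(lo - s, hi - s))
        out[tuple(dst)] = vol[tuple(src)]
        return out

    return PhantomSubject(
        subject_id=subject.subject_id,
        volumes={m: crop(v) for m, v in subject.volumes.items()},
        roi_mask=crop(mask),
        idh_label=subject.idh_label,
        grade_label=subject.grade_label,
        features=subject.features.copy(),
    )


# -- cohort I/O (NIfTI + CSV + JSON manifest) -------------------------------

def save_cohort(subjects: list[PhantomSubject], out_dir) -> None:
    import nibabel as nib
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    manifest = []
    rows = {}
    for s in subjects:
        sdir = out / s.subject_id
        sdir.mkdir(exist_ok=True)
        for m in MODALITIES:
            nib.save(nib.Nifti1Image(s.volumes[m].astype(np.float32), affine),
                     str(sdir / f"{m}.nii.gz"))
        nib.save(nib.Nifti1Image(s.roi_mask.astype(np.int16), affine),
                 str(sdir / "mask.nii.gz"))
        manifest.append({"subject_id": s.subject_id, "idh_label": s.idh_label,
                         "grade_label": s.grade_label})
        rows[s.subject_id] = s.features
    cols = [f"radiomic_{j:03d}" for j in range(99)] + ["age", "sex"]
    pd.DataFrame.from_dict(rows, orient="index", columns=cols).rename_axis(
        "subject_id").to_csv(out / "features.csv")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_cohort(in_dir) -> list[PhantomSubject]:
    import nibabel as nib
    from pathlib import Path

    root = Path(in_dir)
    manifest = json.loads((root / "manifest.json").read_text())
    feats = pd.read_csv(root / "features.csv", index_col="subject_id")
    subjects = []
    for entry in manifest:
        sid = entry["subject_id"]
        sdir = root / sid
        volumes = {
            m: np.asarray(nib.load(str(sdir / f"{m}.nii.gz")).dataobj,
                          dtype=np.float64)
            for m in MODALITIES
        }
        mask = np.asarray(nib.load(str(sdir / "mask.nii.gz")).dataobj,
                          dtype=np.int16)
        subjects.append(PhantomSubject(
            subject_id=sid, volumes=volumes, roi_mask=mask,
            idh_label=int(entry["idh_label"]), grade_label=int(entry["grade_label"]),
            features=feats.loc[sid].to_numpy(dtype=np.float64)))
    return subjects
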