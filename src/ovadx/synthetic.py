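"""Synthetic phantoms and cohorts.

Two generators stand in for data that cannot be shipped: (a) MRI-like 2D
slices containing elliptical, ring-shaped, or fuzzy-boundary "tumors" on a
textured background, paired with gold-standard binary masks; (b) a
case/control laboratory cohort of 25 serum indicators plus 3 demographic
fields, built on a 3-latent-factor model (tumor-marker/hormone,
glucose-lipid metabolism, inflammation) so that a correlation PCA finds
exactly three dominant components.

All randomness flows from an explicit integer seed per call; identical
seeds reproduce outputs bit for bit.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "TUMOR_SHAPES",
    "INDICATOR_NAMES",
    "NEGATIVE_DIRECTION_INDICATORS",
    "PhantomSpec",
    "SlicePair",
    "PhantomDataset",
    "CohortSpec",
    "generate_phantom",
    "generate_phantom_dataset",
    "generate_cohort",
    "write_phantom_dataset",
    "read_phantom_dataset",
    "write_phantom_nifti",
    "write_cohort_csv",
    "read_cohort_csv",
]

TUMOR_SHAPES = ("ellipse", "ring", "fuzzy")

#: The 25 laboratory indicators of the diagnostic panel, grouped as
#: tumor markers (CA125..SSC), blood-cell parameters (NLR..DD), sex
#: hormones (β-HCG..FSH), biochemistry (AGR..FPG) and lipid metabolism.
INDICATOR_NAMES = (
    "CA125", "CA15-3", "CA72-4", "CA19-9", "CEA", "AFP", "SF", "SSC",
    "NLR", "PLR", "RDW", "Fib", "DD",
    "β-HCG", "E2", "P", "LH", "FSH",
    "AGR", "PA", "CRP", "FPG",
    "TG", "TC", "LDL-C/HDL-C",
)

#: Indicators whose mean is LOWER in the cancer group than in controls.
NEGATIVE_DIRECTION_INDICATORS = frozenset({"E2", "P", "AGR", "PA", "TC"})

DEMOGRAPHIC_NAMES = ("age", "menopausal", "pregnancies")
SUBGROUPS = ("case", "other-malignant", "benign", "healthy")

COHORT_COLUMNS = INDICATOR_NAMES + DEMOGRAPHIC_NAMES + ("label", "subgroup", "stage")


# --------------------------------------------------------------------------
# Phantom slices
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic slice/mask pair.

    ``tumor_intensity_contrast`` is the mean intensity offset between
    tumor and background before noise; ``background_texture_scale`` is
    the Gaussian correlation length (pixels) of the background texture.
    """

    image_size: int = 64
    tumor_shape: str = "ellipse"
    tumor_intensity_contrast: float = 0.5
    noise_sd: float = 0.05
    background_texture_scale: float = 6.0
    tumor_radius: tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 32:
            raise ValueError(f"image_size must be >= 32, got {self.image_size}")
        if self.tumor_shape not in TUMOR_SHAPES:
            raise ValueError(
                f"unknown tumor_shape {self.tumor_shape!r}; "
                f"options are {', '.join(TUMOR_SHAPES)}"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass(frozen=True)
class SlicePair:
    """One grayscale slice with its gold-standard binary mask."""

    image: np.ndarray
    mask: np.ndarray
    id: str

    def __post_init__(self) -> None:
        if self.image.shape != self.mask.shape:
            raise ValueError(
                f"image shape {self.image.shape} != mask shape {self.mask.shape}"
            )
        vals = np.unique(self.mask)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mask must contain only values {0, 1}")


@dataclass(frozen=True)
class PhantomDataset:
    pairs: tuple[SlicePair, ...]

    def __post_init__(self) -> None:
        ids = [p.id for p in self.pairs]
        if len(set(ids)) != len(ids):
            raise ValueError("pair ids must be unique")

    @property
    def N(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    def __getitem__(self, i):
        return self.pairs[i]


def _ellipse_mask(n: int, center, axes, theta: float) -> np.ndarray:
    """Filled rotated ellipse as a boolean mask (row-major coordinates)."""
    rr, cc = np.mgrid[0:n, 0:n]
    dr = rr - center[0]
    dc = cc - center[1]
    ct, st = np.cos(theta), np.sin(theta)
    u = dr * ct + dc * st
    v = -dr * st + dc * ct
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


def _tumor_geometry(n: int, rng: np.random.Generator, radius=None):
    """Random ellipse parameters guaranteed to fit inside the image.

    Semi-axes default to the size-proportional range [n/8, n/5]; pass an
    absolute ``radius`` range to decouple tumor size from image size
    (needed when one phantom is cropped at several ROI sizes).
    """
    lo, hi = radius if radius is not None else (n / 8, n / 5)
    a = rng.uniform(lo, hi)
    b = rng.uniform(lo, hi)
    theta = rng.uniform(0, np.pi)
    margin = max(a, b) + 2
    cr = rng.uniform(margin, n - margin)
    cc = rng.uniform(margin, n - margin)
    return (cr, cc), (a, b), theta


def generate_phantom(spec: PhantomSpec) -> SlicePair:
    """Generate one slice/mask pair according to ``spec``.

    The background is a smooth zero-mean Gaussian random field on a 0.35
    base level; the tumor region is raised by ``tumor_intensity_contrast``
    (for the fuzzy shape the raise follows a smoothed ramp and the gold
    mask is the ramp thresholded at 0.5). Additive Gaussian noise with
    ``noise_sd`` comes last; intensities are clipped to be nonnegative.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.image_size
    center, axes, theta = _tumor_geometry(n, rng, spec.tumor_radius)

    texture = ndimage.gaussian_filter(
        rng.standard_normal((n, n)), spec.background_texture_scale
    )
    sd = texture.std()
    if sd > 0:
        texture *= 0.02 / sd
    image = 0.35 + texture

    outer = _ellipse_mask(n, center, axes, theta)
    if spec.tumor_shape == "ellipse":
        mask = outer
        image = image + spec.tumor_intensity_contrast * mask
    elif spec.tumor_shape == "ring":
        inner = _ellipse_mask(n, center, (0.5 * axes[0], 0.5 * axes[1]), theta)
        mask = outer & ~inner
        image = image + spec.tumor_intensity_contrast * mask
    else:  # fuzzy
        ramp = ndimage.gaussian_filter(outer.astype(float), max(n / 32.0, 1.5))
        mask = ramp >= 0.5
        image = image + spec.tumor_intensity_contrast * ramp

    if spec.noise_sd > 0:
        image = image + spec.noise_sd * rng.standard_normal((n, n))
    image = np.clip(image, 0.0, None)

    if not mask.any():
        raise RuntimeError("generated tumor mask is empty")  # pragma: no cover
    pair_id = f"{spec.tumor_shape}-{spec.seed}"
    return SlicePair(image=image, mask=mask.astype(np.uint8), id=pair_id)


def generate_phantom_dataset(
    spec: PhantomSpec,
    N: int,
    shape_mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
) -> PhantomDataset:
    """Generate ``N`` phantoms with shape-class proportions ``shape_mix``.

    ``shape_mix`` gives the proportions of (ellipse, ring, fuzzy); counts
    follow the largest-remainder rule so they match within rounding. Each
    pair gets its own child seed spawned deterministically from
    ``spec.seed``.
    """
    if N < 1:
        raise ValueError("cannot generate an empty dataset (N must be >= 1)")
    mix = np.asarray(shape_mix, dtype=float)
    if mix.shape != (3,) or not np.isclose(mix.sum(), 1.0):
        raise ValueError("shape_mix must be 3 proportions summing to 1")

    ideal = mix * N
    counts = np.floor(ideal).astype(int)
    order = np.argsort(-(ideal - counts))
    for k in order[: N - counts.sum()]:
        counts[k] += 1

    shapes = [s for s, c in zip(TUMOR_SHAPES, counts) for _ in range(c)]
    child_seeds = np.random.SeedSequence(spec.seed).generate_state(N) % (2**31)
    pairs = []
    for i, (shape, child) in enumerate(zip(shapes, child_seeds)):
        sub = replace(spec, tumor_shape=shape, seed=int(child))
        pair = generate_phantom(sub)
        pairs.append(replace(pair, id=f"{i:04d}-{pair.id}"))
    return PhantomDataset(pairs=tuple(pairs))


# --------------------------------------------------------------------------
# Cohorts
# --------------------------------------------------------------------------

def _default_factor_loadings() -> dict[str, tuple[float, float, float]]:
    """Loadings of each indicator on the 3 latent factors.

    Factor 1: gynecological tumor markers and sex hormones; factor 2:
    glucose/lipid metabolism; factor 3: inflammatory status. Magnitude
    0.8 on the home factor with noise sd 0.6 keeps unit total variance.
    """
    factor_of = {
        # factor 1 — tumor markers + hormones
        "CA125": 0, "CA15-3": 0, "CA72-4": 0, "CA19-9": 0, "CEA": 0,
        "AFP": 0, "SF": 0, "SSC": 0, "β-HCG": 0, "E2": 0, "P": 0,
        "LH": 0, "FSH": 0,
        # factor 2 — glucose and lipid metabolism
        "FPG": 1, "TG": 1, "TC": 1, "LDL-C/HDL-C": 1, "AGR": 1, "PA": 1,
        # factor 3 — inflammation
        "NLR": 2, "PLR": 2, "RDW": 2, "Fib": 2, "DD": 2, "CRP": 2,
    }
    return {name: tuple(0.8 if f == factor_of[name] else 0.0 for f in range(3))
            for name in INDICATOR_NAMES}


def _default_effect_directions() -> dict[str, float]:
    return {name: (-1.0 if name in NEGATIVE_DIRECTION_INDICATORS else 1.0)
            for name in INDICATOR_NAMES}


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic case/control cohort.

    Default sizes mirror the study population: 185 cases and control
    subgroups of 138 (other malignant), 339 (benign), 92 (healthy).
    ``effect_size`` scales ``case_effect_directions`` (units of the
    within-group sd); 0 gives a null cohort.
    """

    n_cases: int = 185
    n_controls_by_subgroup: tuple[int, int, int] = (138, 339, 92)
    indicator_names: tuple[str, ...] = INDICATOR_NAMES
    latent_factor_loadings: dict[str, tuple[float, float, float]] = field(
        default_factory=_default_factor_loadings
    )
    case_effect_directions: dict[str, float] = field(
        default_factory=_default_effect_directions
    )
    effect_size: float = 1.0
    noise_sd: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 0 or any(c < 0 for c in self.n_controls_by_subgroup):
            raise ValueError("cohort counts must be nonnegative")
        for d in (self.latent_factor_loadings, self.case_effect_directions):
            unknown = set(d) - set(self.indicator_names)
            if unknown:
                raise ValueError(
                    f"unknown indicator(s) in spec: {sorted(unknown)}"
                )
            missing = set(self.indicator_names) - set(d)
            if missing:
                raise ValueError(
                    f"indicator(s) missing from spec mapping: {sorted(missing)}"
                )


# Modest subgroup baseline shifts on the tumor-marker factor block: other
# malignancies raise markers most among controls, benign disease a little.
_SUBGROUP_MARKER_SHIFT = {"other-malignant": 0.4, "benign": 0.2, "healthy": 0.0}

_AGE_RANGE = {
    "case": (16, 83),
    "other-malignant": (27, 85),
    "benign": (18, 85),
    "healthy": (20, 84),
}


def generate_cohort(spec: CohortSpec):
    """Generate a labeled cohort table (pandas DataFrame).

    Each indicator value is ``subgroup baseline + case effect +
    Σ loading·factor + noise`` with standard-normal latent factors drawn
    per subject. Demographics are drawn independently of the indicators;
    cases additionally carry a uniformly assigned FIGO stage (I–IV).
    """
    import pandas as pd

    rng = np.random.default_rng(spec.seed)
    names = list(spec.indicator_names)
    p = len(names)
    loadings = np.array([spec.latent_factor_loadings[n] for n in names])
    directions = np.array([spec.case_effect_directions[n] for n in names])
    marker_block = np.array(
        [1.0 if spec.latent_factor_loadings[n][0] != 0 else 0.0 for n in names]
    )

    groups = [("case", spec.n_cases)] + [
        (sg, c) for sg, c in zip(SUBGROUPS[1:], spec.n_controls_by_subgroup)
    ]
    frames = []
    for subgroup, count in groups:
        if count == 0:
            continue
        factors = rng.standard_normal((count, 3))
        noise = spec.noise_sd * rng.standard_normal((count, p))
        baseline = np.zeros(p)
        if subgroup == "case":
            baseline = spec.effect_size * directions
        else:
            baseline = _SUBGROUP_MARKER_SHIFT[subgroup] * marker_block
        values = baseline + factors @ loadings.T + noise

        lo, hi = _AGE_RANGE[subgroup]
        age = rng.integers(lo, hi + 1, size=count)
        menopausal = (age > 50).astype(int) ^ (rng.random(count) < 0.1).astype(int)
        pregnancies = rng.poisson(2.0, size=count)
        df = pd.DataFrame(values, columns=names)
        df["age"] = age
        df["menopausal"] = menopausal
        df["pregnancies"] = pregnancies
        df["label"] = "case" if subgroup == "case" else "control"
        df["subgroup"] = subgroup
        if subgroup == "case":
            df["stage"] = rng.choice(["I", "II", "III", "IV"], size=count)
        else:
            df["stage"] = ""
        frames.append(df)
    if not frames:
        raise ValueError("cohort spec produced no rows")
    table = pd.concat(frames, ignore_index=True)
    return table


# --------------------------------------------------------------------------
# On-disk formats
# --------------------------------------------------------------------------

def write_phantom_dataset(dataset: PhantomDataset, out_dir) -> Path:
    """Write paired PNGs (16-bit image, 8-bit {0,255} mask) plus manifest CSV.

    Image intensities are min-max scaled per slice into the 16-bit range.
    Returns the manifest path.
    """
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "image_path", "mask_path", "shape_class"])
        for pair in dataset:
            img = pair.image.astype(float)
            span = img.max() - img.min()
            scaled = (img - img.min()) / span if span > 0 else np.zeros_like(img)
            img16 = (scaled * 65535).round().astype(np.uint16)
            mask8 = (pair.mask * 255).astype(np.uint8)
            ipath = out_dir / f"{pair.id}_image.png"
            mpath = out_dir / f"{pair.id}_mask.png"
            Image.fromarray(img16).save(ipath)  # 16-bit grayscale ("I;16")
            Image.fromarray(mask8, mode="L").save(mpath)
            shape_class = next(
                (s for s in TUMOR_SHAPES if s in pair.id), "unknown"
            )
            writer.writerow([pair.id, ipath.name, mpath.name, shape_class])
    return manifest


def read_phantom_dataset(manifest_path) -> PhantomDataset:
    """Read a dataset written by :func:`write_phantom_dataset`."""
    from PIL import Image

    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    pairs = []
    with open(manifest_path, newline="") as fh:
        for row in csv.DictReader(fh):
            image = np.asarray(Image.open(base / row["image_path"]), dtype=float)
            image /= 65535.0
            mask = (np.asarray(Image.open(base / row["mask_path"])) > 127).astype(
                np.uint8
            )
            pairs.append(SlicePair(image=image, mask=mask, id=row["id"]))
    return PhantomDataset(pairs=tuple(pairs))


def write_phantom_nifti(dataset: PhantomDataset, out_dir) -> list[Path]:
    """Optional NIfTI export (one single-slice volume per pair) for 3D tools."""
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for pair in dataset:
        for kind, arr in (("image", pair.image), ("mask", pair.mask)):
            vol = np.asarray(arr, dtype=np.float32)[:, :, None]
            path = out_dir / f"{pair.id}_{kind}.nii"
            nib.save(nib.Nifti1Image(vol, affine=np.eye(4)), path)
            paths.append(path)
    return paths


def write_cohort_csv(table, path) -> Path:
    """Write a cohort with the fixed documented column order."""
    path = Path(path)
    cols = [c for c in COHORT_COLUMNS if c in table.columns]
    table[cols].to_csv(path, index=False)
    return path


def read_cohort_csv(path):
    import pandas as pd

    table = pd.read_csv(path, keep_default_na=False)
    missing = [c for c in COHORT_COLUMNS[:-1] if c not in table.columns]
    if missing:
        warnings.warn(f"cohort file lacks expected columns: {missing}")
    return table
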