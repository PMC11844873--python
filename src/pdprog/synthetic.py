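"""Synthetic study generator: fMRI volumes with known local-coherence and
band-power ground truth, label atlases, motion traces, and longitudinal
cohorts driven by a known linear generative model.

The generator emulates the inputs of a severity-prediction study without any
real data.  Each region's voxel timeseries is a mixture
``sqrt(rho) * latent + sqrt(1 - rho) * private noise`` of a shared regional
latent signal and voxel-private noise, both spectrally shaped so that a
fraction ``phi`` of their power lies inside the 0.01-0.1 Hz analysis band:
``rho`` is the ReHo ground truth (perfect coherence at rho = 1, chance-level
concordance at rho = 0) and ``sqrt(phi)`` the fALFF ground truth.  Cohort
totals follow a stated linear model over encoded clinical/demographic
features and regional imaging features with Gaussian noise of known variance,
so the theoretical R2 (explained / total variance) of every target is known.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import BrainMask, Image3D, Image4D, LabelAtlas
from .features import (
    DEFAULT_BAND,
    ReHoParams,
    SpectralParams,
    compute_alff_falff,
    compute_reho,
    zscore_map,
)
from .confounds import MotionParams
from .parcellation import extract_regional_means

__all__ = [
    "FMRISynthConfig",
    "CohortSynthConfig",
    "GroundTruth",
    "SyntheticStudy",
    "generate_fmri",
    "generate_motion",
    "generate_cohort",
    "make_block_atlas",
    "split_atlas",
    "calibrate_noise_sd",
    "step_sd_for_mean_fd",
    "simulate_study",
]

SCORE_MAX = 199  # maximum attainable MDS-UPDRS total
# Fixed Dirichlet concentration for decomposing a total into parts
# Ia, Ib, II, III, IV (part III dominates, part IV is small and often absent).
PART_DIRICHLET = np.array([2.0, 2.0, 5.0, 10.0, 0.7])
PART_NAMES = ["NP1RTOT", "NP1PTOT", "NP2TOT", "NP3TOT", "NP4TOT"]
FOLLOWUP_OFFSETS = {"year1": 365, "year2": 730, "year4": 1460}
DATE_JITTER_DAYS = 45  # keeps every synthetic visit inside the +/- 60 day window


@dataclass
class FMRISynthConfig:
    """Parameters of one synthetic 4D acquisition."""

    grid_shape: tuple[int, int, int] = (12, 12, 12)
    n_timepoints: int = 120
    repetition_time: float = 2.4
    coherence_by_region: dict[int, float] = field(default_factory=dict)
    inband_fraction_by_region: dict[int, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(s < 3 for s in self.grid_shape):
            raise ValueError("grid_shape must be 3 ints, each >= 3")
        if self.n_timepoints < 16:
            raise ValueError("need n_timepoints >= 16")
        if self.repetition_time <= 0:
            raise ValueError("repetition_time must be positive")
        for name, mapping in (
            ("coherence", self.coherence_by_region),
            ("inband fraction", self.inband_fraction_by_region),
        ):
            for lab, v in mapping.items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"{name} for region {lab} must lie in [0, 1], got {v}")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")


@dataclass
class CohortSynthConfig:
    """Generative model of the longitudinal cohort.

    ``beta_clinical`` and ``beta_imaging`` are weights (score points per
    sample SD of the feature) applied to sample-standardised features;
    ``alpha_baseline_score`` multiplies the raw baseline total in the
    follow-up model.  ``retention`` gives the non-increasing fractions of the
    baseline cohort retained at Year 1/2/4.
    """

    n_baseline: int = 120
    retention: tuple[float, float, float] = (51 / 82, 41 / 82, 30 / 82)
    beta_clinical: dict[str, float] = field(default_factory=dict)
    beta_imaging: dict[str, float] = field(default_factory=dict)
    beta_imaging_followup: dict[str, float] | None = None
    alpha_baseline_score: float = 0.0
    noise_sd: float = 8.0
    noise_sd_followup: float | None = None
    target_r2: float | None = None
    target_r2_followup: float | None = None
    intercept: float = 34.0
    intercept_followup: float = 5.0
    np4_missing_prob: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_baseline < 1:
            raise ValueError("n_baseline must be positive")
        if len(self.retention) != 3 or not all(0 < r <= 1 for r in self.retention):
            raise ValueError("retention must be 3 fractions in (0, 1]")
        if any(a < b for a, b in zip(self.retention, self.retention[1:])):
            raise ValueError("retention must be non-increasing (longitudinal attrition)")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be positive")
        if not 0.0 <= self.np4_missing_prob <= 1.0:
            raise ValueError("np4_missing_prob must lie in [0, 1]")


@dataclass
class GroundTruth:
    """What the generator knows that the pipeline must recover."""

    coherence_map: np.ndarray | None = None
    inband_by_region: dict[int, float] = field(default_factory=dict)
    beta_clinical: dict[str, float] = field(default_factory=dict)
    beta_imaging: dict[str, float] = field(default_factory=dict)
    alpha_baseline_score: float = 0.0
    noise_sd: float = 0.0
    theoretical_r2: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, r2 in self.theoretical_r2.items():
            if not 0.0 <= r2 <= 1.0:
                raise ValueError(f"theoretical R2 for {name!r} must lie in [0, 1], got {r2}")


def make_block_atlas(
    grid_shape: tuple[int, int, int] = (12, 12, 12),
    n_regions: int = 6,
    border: int = 1,
    affine: np.ndarray | None = None,
    name_prefix: str = "region",
) -> LabelAtlas:
    """Deterministic slab atlas: the grid interior (inside a background
    border) split into ``n_regions`` contiguous slabs along the z axis."""
    if affine is None:
        affine = np.diag([3.0, 3.0, 3.0, 1.0])
    data = np.zeros(grid_shape, dtype=np.int32)
    z0, z1 = border, grid_shape[2] - border
    edges = np.linspace(z0, z1, n_regions + 1).round().astype(int)
    sl = slice(border, -border) if border else slice(None)
    for lab in range(1, n_regions + 1):
        data[sl, sl, edges[lab - 1] : edges[lab]] = lab
    labels = {lab: f"{name_prefix}_{lab}" for lab in range(1, n_regions + 1)}
    return LabelAtlas(data, affine, labels)


def split_atlas(atlas: LabelAtlas, axis: int = 0) -> LabelAtlas:
    """Refine an atlas by halving every region along one voxel axis, yielding
    a child parcellation whose unions reproduce the parent regions."""
    data = np.zeros(atlas.shape, dtype=np.int32)
    labels: dict[int, str] = {}
    mid = atlas.shape[axis] // 2
    idx = np.indices(atlas.shape)[axis]
    for i, lab in enumerate(atlas.label_ids):
        lo, hi = 2 * i + 1, 2 * i + 2
        region = atlas.data == lab
        data[region & (idx < mid)] = lo
        data[region & (idx >= mid)] = hi
        labels[lo] = f"{atlas.labels[lab]}_a"
        labels[hi] = f"{atlas.labels[lab]}_b"
    return LabelAtlas(data, atlas.affine, labels)


def _shaped_noise(
    rng: np.random.Generator, rows: int, n: int, tr: float, phi: float
) -> np.ndarray:
    """Unit-variance series with an in-band power fraction of ``phi``.

    In-band and out-of-band Gaussian components are built in the frequency
    domain (DC excluded from both so the series is zero-mean) and mixed as
    sqrt(phi) / sqrt(1 - phi).
    """
    freqs = np.fft.rfftfreq(n, d=tr)
    lo, hi = DEFAULT_BAND
    inband = (freqs >= lo - 1e-12) & (freqs <= hi + 1e-12)
    inband[0] = False
    outband = ~inband
    outband[0] = False
    if not inband.any():
        raise ValueError(
            f"no FFT bin inside the band {DEFAULT_BAND}: n_timepoints={n} too small "
            f"at repetition_time={tr}"
        )

    def _component(keep: np.ndarray) -> np.ndarray:
        white = rng.standard_normal((rows, n))
        spec = np.fft.rfft(white, axis=1)
        spec[:, ~keep] = 0.0
        series = np.fft.irfft(spec, n=n, axis=1)
        sd = series.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        return series / sd

    out = np.zeros((rows, n))
    if phi > 0:
        out += np.sqrt(phi) * _component(inband)
    if phi < 1:
        out += np.sqrt(1.0 - phi) * _component(outband)
    return out


def generate_fmri(
    config: FMRISynthConfig, atlas: LabelAtlas
) -> tuple[Image4D, BrainMask, GroundTruth]:
    """Synthesise a 4D volume over an atlas with known rho / phi per region.

    Unlisted regions default to rho = 0 (independent voxels) and phi = 0.5.
    Background voxels carry white noise; the mask covers all labelled voxels.
    Bit-identical output for identical seeds.
    """
    if atlas.shape != tuple(config.grid_shape):
        raise ValueError(
            f"atlas grid {atlas.shape} does not match config grid {tuple(config.grid_shape)}"
        )
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n = config.n_timepoints
    tr = config.repetition_time
    data = np.zeros((*config.grid_shape, n))
    coherence_map = np.zeros(config.grid_shape)

    background = atlas.data == 0
    data[background] = rng.standard_normal((int(background.sum()), n))
    for lab in atlas.label_ids:
        voxels = atlas.data == lab
        v = int(voxels.sum())
        if v == 0:
            continue
        rho = float(config.coherence_by_region.get(lab, 0.0))
        phi = float(config.inband_fraction_by_region.get(lab, 0.5))
        latent = _shaped_noise(rng, 1, n, tr, phi)
        private = _shaped_noise(rng, v, n, tr, phi)
        data[voxels] = np.sqrt(rho) * latent + np.sqrt(1.0 - rho) * private
        coherence_map[voxels] = rho

    mask = BrainMask(atlas.data > 0, atlas.affine)
    truth = GroundTruth(
        coherence_map=coherence_map,
        inband_by_region={
            lab: float(config.inband_fraction_by_region.get(lab, 0.5))
            for lab in atlas.label_ids
        },
    )
    return Image4D(data, atlas.affine, tr), mask, truth


def step_sd_for_mean_fd(
    target_mean_fd: float, radius: float = 50.0
) -> tuple[float, float]:
    """Random-walk step SDs (translation mm, rotation rad) whose expected FD
    equals ``target_mean_fd``, split evenly between translations and
    rotations.  E|step| = sd * sqrt(2/pi) for a Gaussian step."""
    c = np.sqrt(2.0 / np.pi)
    trans_sd = target_mean_fd / (6.0 * c)
    rot_sd = target_mean_fd / (6.0 * c * radius)
    return float(trans_sd), float(rot_sd)


def generate_motion(
    n_timepoints: int, step_sd: float | tuple[float, float], seed: int = 0
) -> MotionParams:
    """Random-walk 6-parameter motion trace (3 translations mm, 3 rotations
    rad), starting at zero.  ``step_sd`` may be a scalar (applied to both
    blocks) or a (translation, rotation) pair."""
    if n_timepoints < 2:
        raise ValueError("need at least 2 timepoints")
    if np.isscalar(step_sd):
        trans_sd = rot_sd = float(step_sd)
    else:
        trans_sd, rot_sd = (float(s) for s in step_sd)
    if trans_sd < 0 or rot_sd < 0:
        raise ValueError("step_sd must be non-negative")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    steps = rng.standard_normal((n_timepoints - 1, 6))
    steps[:, :3] *= trans_sd
    steps[:, 3:] *= rot_sd
    trace = np.vstack([np.zeros(6), np.cumsum(steps, axis=0)])
    return MotionParams(trace, convention="translations_first")


def calibrate_noise_sd(predictor: np.ndarray, target_r2: float) -> float:
    """Noise SD making explained/total variance of ``predictor + noise`` equal
    ``target_r2`` (closed form: sd = sd(pred) * sqrt((1-R2)/R2))."""
    if not 0.0 < target_r2 < 1.0:
        raise ValueError("target_r2 must lie strictly between 0 and 1")
    pred_sd = float(np.asarray(predictor, dtype=float).std())
    if pred_sd == 0:
        raise ValueError("constant predictor cannot reach a positive R2")
    return pred_sd * np.sqrt((1.0 - target_r2) / target_r2)


def _standardise(df: pd.DataFrame) -> pd.DataFrame:
    sd = df.std(ddof=0).replace(0.0, 1.0)
    return (df - df.mean()) / sd


def _decompose_total(rng: np.random.Generator, total: int, np4_missing: bool) -> dict:
    """Split a total into the five parts with a fixed Dirichlet; a missing
    part IV is generated as zero so the missing-to-zero rule reconstructs the
    total exactly."""
    alpha = PART_DIRICHLET.copy()
    if np4_missing:
        alpha = alpha[:4]
    fracs = rng.dirichlet(alpha)
    parts = np.floor(fracs * total).astype(int)
    remainder = int(total - parts.sum())
    order = np.argsort(-(fracs * total - parts))
    for j in range(remainder):
        parts[order[j % len(parts)]] += 1
    row = dict(zip(PART_NAMES[: len(parts)], (int(p) for p in parts)))
    if np4_missing:
        row["NP4TOT"] = np.nan
    return row


def _draw_demographics(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Clinical/demographic covariates with marginals mirroring a typical
    early-PD cohort (age ~62, two-thirds male, ~15.6 y education, ...)."""
    return pd.DataFrame(
        {
            "AGE": np.clip(rng.normal(62.1, 9.8, n), 35, 90).round(1),
            "SEX": rng.choice(["male", "female"], n, p=[0.67, 0.33]),
            "EDUCYRS": np.clip(rng.normal(15.6, 3.0, n), 6, 24).round(0),
            "HANDED": rng.choice(["right", "left", "ambidextrous"], n, p=[0.89, 0.09, 0.02]),
            "RACE": rng.choice(["white", "black", "asian", "other"], n, p=[0.95, 0.02, 0.02, 0.01]),
            "ETHNICITY": rng.choice(["not_hispanic", "hispanic"], n, p=[0.99, 0.01]),
            "DOMSIDE": rng.choice(["left", "right"], n, p=[0.45, 0.55]),
            "TREMOR": rng.binomial(1, 0.75, n),
            "RIGIDITY": rng.binomial(1, 0.8, n),
            "POSTURAL_INSTABILITY": rng.binomial(1, 0.2, n),
            "DISEASE_DURATION": np.clip(rng.normal(770, 565, n), 30, None).round(0),
            "SYMPTOM_DURATION": np.clip(rng.normal(900, 600, n), 60, None).round(0),
            "GDS": np.clip(rng.normal(5.4, 1.4, n), 0, 15).round(0),
            "MOCA": np.clip(rng.normal(26.7, 2.8, n), 10, 30).round(0),
            "PAG_NAME": "NUPDRS3A",  # ON-medication motor exam
        }
    )


def generate_cohort(
    config: CohortSynthConfig, regional_features: pd.DataFrame
) -> tuple[pd.DataFrame, GroundTruth]:
    """Longitudinal cohort table whose totals follow the configured linear
    model over clinical/demographic and regional imaging features.

    Baseline total = intercept + sum(beta * standardised feature) + noise,
    clipped to [0, 199] and rounded; follow-up totals add
    ``alpha_baseline_score * baseline total`` and their own imaging terms.
    Visit dates sit at 365/730/1460 days + uniform jitter within +/- 45 days;
    part scores are decomposed from the total with a fixed Dirichlet and part
    IV is generated as missing (value zero) with the configured probability.
    """
    n = config.n_baseline
    if len(regional_features) < n:
        raise ValueError(
            f"regional_features has {len(regional_features)} rows, need >= {n}"
        )
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    imaging = regional_features.iloc[:n].copy()
    patnos = [f"P{i:04d}" for i in range(n)]
    imaging.index = patnos

    demo = _draw_demographics(rng, n)
    demo.index = pd.Index(patnos)
    encoded = demo.assign(
        SEX=(demo["SEX"] == "male").astype(float),
        HANDED=(demo["HANDED"] == "right").astype(float),
        DOMSIDE=(demo["DOMSIDE"] == "right").astype(float),
    ).drop(columns=["RACE", "ETHNICITY", "PAG_NAME"])
    pool = pd.concat([encoded.astype(float), imaging], axis=1)

    for beta_map, label in (
        (config.beta_clinical, "beta_clinical"),
        (config.beta_imaging, "beta_imaging"),
        (config.beta_imaging_followup or {}, "beta_imaging_followup"),
    ):
        unknown = [c for c in beta_map if c not in pool.columns]
        if unknown:
            raise ValueError(f"{label} names not found in features: {unknown}")

    std_pool = _standardise(pool)

    def _linear(beta_map: dict[str, float]) -> np.ndarray:
        out = np.zeros(n)
        for name, beta in beta_map.items():
            out += beta * std_pool[name].to_numpy()
        return out

    base_pred = config.intercept + _linear(config.beta_clinical) + _linear(config.beta_imaging)
    noise_sd = (
        calibrate_noise_sd(base_pred, config.target_r2)
        if config.target_r2 is not None
        else config.noise_sd
    )
    base_noise = rng.normal(0.0, noise_sd, n)
    base_total = np.clip(np.rint(base_pred + base_noise), 0, SCORE_MAX).astype(int)

    base_date = pd.Timestamp("2020-01-06")
    rows = []
    np4_missing = rng.random(n) < config.np4_missing_prob
    for i, patno in enumerate(patnos):
        row = {
            "PATNO": patno,
            "EVENT_ID": "BL",
            "INFODT": base_date.date().isoformat(),
            **_decompose_total(rng, int(base_total[i]), bool(np4_missing[i])),
            "BASELINE_UPDRS": int(base_total[i]),
            **demo.loc[patno].to_dict(),
        }
        rows.append(row)

    beta_img_fu = (
        config.beta_imaging_followup
        if config.beta_imaging_followup is not None
        else config.beta_imaging
    )
    theoretical = {
        "baseline": float(base_pred.var() / (base_pred.var() + noise_sd**2))
    }
    event_ids = {"year1": "V04", "year2": "V06", "year4": "V10"}
    fu_pred = (
        config.intercept_followup
        + config.alpha_baseline_score * base_total
        + _linear(beta_img_fu)
    )
    if config.target_r2_followup is not None:
        fu_noise_sd = calibrate_noise_sd(fu_pred, config.target_r2_followup)
    else:
        fu_noise_sd = config.noise_sd_followup or noise_sd
    for k, (name, offset) in enumerate(FOLLOWUP_OFFSETS.items()):
        n_keep = int(round(n * config.retention[k]))
        keep = list(range(n_keep))
        fu_noise = rng.normal(0.0, fu_noise_sd, n)
        fu_total = np.clip(np.rint(fu_pred + fu_noise), 0, SCORE_MAX).astype(int)
        jitter = rng.integers(-DATE_JITTER_DAYS, DATE_JITTER_DAYS + 1, n)
        np4_missing_fu = rng.random(n) < config.np4_missing_prob
        kept_pred = fu_pred[keep]
        theoretical[name] = float(
            kept_pred.var() / (kept_pred.var() + fu_noise_sd**2)
        )
        for i in keep:
            rows.append(
                {
                    "PATNO": patnos[i],
                    "EVENT_ID": event_ids[name],
                    "INFODT": (base_date + pd.Timedelta(days=offset + int(jitter[i])))
                    .date()
                    .isoformat(),
                    **_decompose_total(rng, int(fu_total[i]), bool(np4_missing_fu[i])),
                    "BASELINE_UPDRS": int(base_total[i]),
                    **demo.loc[patnos[i]].to_dict(),
                }
            )

    cohort = pd.DataFrame(rows)
    truth = GroundTruth(
        beta_clinical=dict(config.beta_clinical),
        beta_imaging=dict(config.beta_imaging),
        alpha_baseline_score=config.alpha_baseline_score,
        noise_sd=noise_sd,
        theoretical_r2=theoretical,
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# The shipped synthetic study
# ---------------------------------------------------------------------------

DEFAULT_BETA_CLINICAL = {
    "DISEASE_DURATION": 2.5,
    "SYMPTOM_DURATION": 1.0,
    "MOCA": -2.0,
    "GDS": 1.5,
    "AGE": 1.0,
    "TREMOR": 1.0,
}


@dataclass
class SyntheticStudy:
    """A fully generated study: atlas, cohort, motion, per-participant scan
    configurations (volumes are regenerated deterministically on demand), and
    the default-pipeline regional feature matrices."""

    atlas: LabelAtlas
    parcellations: dict[str, LabelAtlas]
    cohort: pd.DataFrame
    imaging: dict[str, pd.DataFrame]
    fmri_configs: dict[str, FMRISynthConfig]
    motion: dict[str, MotionParams]
    ground_truth: GroundTruth
    feature_type: str = "reho"
    zscore: bool = True

    @property
    def participants(self) -> list[str]:
        return list(self.fmri_configs)

    def fmri_for(self, patno: str) -> tuple[Image4D, BrainMask]:
        img, mask, _ = generate_fmri(self.fmri_configs[patno], self.atlas)
        return img, mask


def _participant_map(
    config: FMRISynthConfig,
    atlas: LabelAtlas,
    feature_type: str,
    zscore: bool,
) -> Image3D:
    img, mask, _ = generate_fmri(config, atlas)
    if feature_type == "reho":
        map3d = compute_reho(img, mask, ReHoParams())
    else:
        alff, falff = compute_alff_falff(img, mask, SpectralParams())
        map3d = alff if feature_type == "alff" else falff
    return zscore_map(map3d, mask) if zscore else map3d


def regional_feature_table(
    study: "SyntheticStudy",
    feature_type: str | None = None,
    zscore: bool | None = None,
) -> dict[str, pd.DataFrame]:
    """Recompute the participants x regions feature matrices for every
    parcellation under the requested feature toggles (defaults: the study's
    own)."""
    feature_type = feature_type or study.feature_type
    zscore = study.zscore if zscore is None else zscore
    tables: dict[str, list[pd.Series]] = {name: [] for name in study.parcellations}
    for patno, config in study.fmri_configs.items():
        map3d = _participant_map(config, study.atlas, feature_type, zscore)
        for name, parc in study.parcellations.items():
            regional = extract_regional_means(map3d, parc, feature_type, patno)
            series = regional.as_named(parc)
            series.name = patno
            tables[name].append(series)
    return {name: pd.DataFrame(rows) for name, rows in tables.items()}


def simulate_study(
    n_participants: int = 120,
    seed: int = 0,
    grid_shape: tuple[int, int, int] = (12, 12, 12),
    n_timepoints: int = 120,
    repetition_time: float = 2.4,
    n_regions: int = 6,
    feature_type: str = "reho",
    zscore: bool = True,
    target_r2: float = 0.5,
    target_r2_followup: float = 0.6,
    alpha_baseline_score: float = 0.8,
    noise_sd: float | None = None,
    retention: tuple[float, float, float] = (51 / 82, 41 / 82, 30 / 82),
    mean_fd: float = 0.258,
    imaging_beta_scale: float = 1.0,
) -> SyntheticStudy:
    """Generate the shipped end-to-end study.

    Per participant, regional coherence rho ~ U(0.1, 0.9) and in-band fraction
    phi ~ U(0.2, 0.8) vary across regions, so the extracted regional features
    carry between-participant signal.  Baseline totals load on clinical
    covariates and on the default-pipeline regional features of the truth
    parcellation; the noise SD is calibrated in closed form so the theoretical
    R2 equals ``target_r2`` (``noise_sd`` overrides the calibration when
    given).  Follow-up totals add ``alpha_baseline_score`` times the baseline
    total.
    """
    master = np.random.SeedSequence(seed)
    atlas = make_block_atlas(grid_shape, n_regions=n_regions)
    parcellations = {
        f"slab{n_regions}": atlas,
        f"split{2 * n_regions}": split_atlas(atlas),
    }

    rng = np.random.default_rng(master.spawn(1)[0])
    configs: dict[str, FMRISynthConfig] = {}
    motion: dict[str, MotionParams] = {}
    step = step_sd_for_mean_fd(mean_fd)
    for i in range(n_participants):
        patno = f"P{i:04d}"
        rho = {lab: float(r) for lab, r in zip(atlas.label_ids, rng.uniform(0.1, 0.9, n_regions))}
        phi = {lab: float(p) for lab, p in zip(atlas.label_ids, rng.uniform(0.2, 0.8, n_regions))}
        configs[patno] = FMRISynthConfig(
            grid_shape=grid_shape,
            n_timepoints=n_timepoints,
            repetition_time=repetition_time,
            coherence_by_region=rho,
            inband_fraction_by_region=phi,
            seed=int(np.random.SeedSequence(seed, spawn_key=(8, i)).generate_state(1)[0] % 2**31),
        )
        motion[patno] = generate_motion(
            n_timepoints,
            step,
            seed=int(np.random.SeedSequence(seed, spawn_key=(9, i)).generate_state(1)[0] % 2**31),
        )

    study = SyntheticStudy(
        atlas=atlas,
        parcellations=parcellations,
        cohort=pd.DataFrame(),
        imaging={},
        fmri_configs=configs,
        motion=motion,
        ground_truth=GroundTruth(),
        feature_type=feature_type,
        zscore=zscore,
    )
    study.imaging = regional_feature_table(study)

    truth_features = study.imaging[f"slab{n_regions}"]
    signs = np.where(np.arange(n_regions) % 2 == 0, 1.0, -1.0)
    beta_imaging = {
        col: float(imaging_beta_scale * s * (2.5 - 0.2 * j))
        for j, (col, s) in enumerate(zip(truth_features.columns, signs))
    }
    beta_img_fu = {col: 0.4 * b for col, b in beta_imaging.items()}

    config = CohortSynthConfig(
        n_baseline=n_participants,
        retention=retention,
        beta_clinical=DEFAULT_BETA_CLINICAL,
        beta_imaging=beta_imaging,
        beta_imaging_followup=beta_img_fu,
        alpha_baseline_score=alpha_baseline_score,
        noise_sd=noise_sd if noise_sd is not None else 8.0,
        target_r2=None if noise_sd is not None else target_r2,
        target_r2_followup=target_r2_followup,
        seed=int(np.random.SeedSequence(seed, spawn_key=(11,)).generate_state(1)[0] % 2**31),
    )
    cohort, truth = generate_cohort(config, truth_features)

    study.cohort = cohort
    study.ground_truth = truth
    study.ground_truth.alpha_baseline_score = alpha_baseline_score
    return study
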