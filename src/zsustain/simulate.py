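"""Synthetic multi-site cohort generator with planted progression trajectories.

Emulates the statistical structure the downstream analysis assumes: control
ROI volumes drawn around covariate- and site-dependent means with unit
population SD (so planted patient deviations are exact z-units), patients
placed on one of two planted event sequences (a cortical-first trajectory
starting in Broca's area and a subcortical-first trajectory starting in the
hippocampus) at a random stage, multi-site additive/multiplicative scanner
effects, and clinical scores (illness duration, PANSS subscales) weakly
coupled to the true stage.

Simulation truth lives in clearly marked ``true_*`` columns that the
inference stages never read (see :data:`TRUTH_COLUMNS`).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .atlas import DEFAULT_ATLAS, ROIAtlas
from .model import (
    EventSequence,
    ZScoreEventModelSpec,
    stage_expectations,
)

__all__ = [
    "ClinicalModel",
    "SimulationConfig",
    "default_trajectories",
    "generate_cohort",
    "generate_clinical",
    "event_spec_for",
    "feature_matrix",
    "write_cohort",
    "read_cohort",
    "TRUTH_COLUMNS",
]

#: Simulation-truth columns; inference code must never read these.
TRUTH_COLUMNS = ("true_subtype", "true_stage")

# ROI onset ranks for the two planted trajectories. Events are ordered by
# onset rank staggered across waypoint waves, so early regions reach z=3
# before late regions cross z=1.
_CORTICAL_FIRST = (
    "Broca's area", "insula", "frontal lobe", "cingulate", "temporal lobe",
    "parietal lobe", "occipital lobe", "sensorimotor", "cerebellum",
    "thalamus", "caudate", "putamen", "pallidum", "accumbens",
    "parahippocampus", "amygdala", "hippocampus",
)
_SUBCORTICAL_FIRST = (
    "hippocampus", "amygdala", "parahippocampus", "accumbens", "caudate",
    "putamen", "pallidum", "thalamus", "temporal lobe", "insula",
    "Broca's area", "frontal lobe", "cingulate", "parietal lobe",
    "occipital lobe", "sensorimotor", "cerebellum",
)
_WAVE_STAGGER = 6.0  # onset-rank gap between successive waypoint waves


def event_spec_for(
    atlas: ROIAtlas = DEFAULT_ATLAS,
    waypoints: tuple[float, ...] = (1.0, 2.0, 3.0),
    z_max: float = 5.0,
    sigma: float = 1.0,
) -> ZScoreEventModelSpec:
    """Event-model specification over an atlas's ROIs."""
    return ZScoreEventModelSpec(
        biomarkers=atlas.names, waypoints=waypoints, z_max=z_max, sigma=sigma
    )


def _trajectory_from_onsets(
    onset_order: tuple[str, ...], spec: ZScoreEventModelSpec
) -> EventSequence:
    rank = {name: i for i, name in enumerate(onset_order)}
    events = [
        (b, w)
        for b in spec.biomarkers
        for w in spec.waypoints
    ]
    events.sort(
        key=lambda ev: (
            rank[ev[0]] + _WAVE_STAGGER * spec.waypoints.index(ev[1]),
            ev[1],
            rank[ev[0]],
        )
    )
    seq = EventSequence(tuple(events))
    seq.validate(spec)
    return seq


def default_trajectories(
    atlas: ROIAtlas = DEFAULT_ATLAS,
    spec: ZScoreEventModelSpec | None = None,
) -> tuple[EventSequence, EventSequence]:
    """The two planted progression sequences.

    Trajectory 1 is cortical-predominant: volume loss starts in Broca's area,
    spreads through fronto-insular cortex and the rest of the neocortex, and
    reaches the subcortex last.  Trajectory 2 is subcortical-predominant:
    loss begins in the hippocampus, spreads to amygdala/parahippocampus, then
    accumbens/caudate, before the cortex.
    """
    spec = spec or event_spec_for(atlas)
    missing = set(spec.biomarkers) - set(_CORTICAL_FIRST)
    if missing:
        raise ValueError(f"default trajectories need the 17-ROI atlas; missing {missing}")
    return (
        _trajectory_from_onsets(_CORTICAL_FIRST, spec),
        _trajectory_from_onsets(_SUBCORTICAL_FIRST, spec),
    )


@dataclass(frozen=True)
class ClinicalModel:
    """Clinical-score generator: duration coupled to stage via a Gaussian
    copula, PANSS subscales as linear-in-duration latent severities with
    subtype-specific slopes (points/year).

    Defaults plant: positive symptoms declining with duration in both
    subtypes; negative and depression/anxiety symptoms worsening with
    duration only in subtype 1.
    """

    stage_duration_rho: float = 0.11
    duration_bin_weights: tuple[float, float, float] = (0.42, 0.26, 0.32)
    late_tail_scale: float = 12.0
    late_tail_cap: float = 35.0
    #: name -> (baseline, per-subtype slope in points/year, noise SD)
    subscales: dict = field(
        default_factory=lambda: {
            "panss_positive": (19.7, (-0.15, -0.15), 6.5),
            "panss_negative": (16.7, (0.15, 0.0), 7.5),
            "panss_general": (37.8, (-0.12, -0.23), 11.5),
            "panss_depression_anxiety": (11.2, (0.065, 0.0), 4.2),
            "panss_cognitive": (10.0, (0.09, 0.05), 4.0),
            "panss_excitement": (8.8, (-0.03, -0.045), 3.4),
        }
    )

    def null(self) -> "ClinicalModel":
        """Same noise structure with every duration trend set to zero."""
        return replace(
            self,
            subscales={k: (b, tuple(0.0 for _ in s), sd) for k, (b, s, sd) in self.subscales.items()},
        )


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the synthetic cohort.

    Sizes, subtype fractions (0.62/0.38), uniform stage occupancy, unit
    z-noise, three sites with additive shifts of +/-0.3 control SD and scale
    factors 0.9/1.0/1.1, and age/age^2/sex/TIV covariate effects.
    """

    n_patients: int = 800
    n_controls: int = 800
    subtype_fractions: tuple[float, ...] = (0.62, 0.38)
    planted_sequences: tuple[EventSequence, ...] | None = None
    stage_probs: tuple[float, ...] | None = None  # over 0..E; None = uniform
    noise_sd: float = 1.0
    n_sites: int = 3
    site_shifts: tuple[float, ...] = (-0.3, 0.0, 0.3)
    site_scales: tuple[float, ...] = (0.9, 1.0, 1.1)
    beta_age: float = -0.02
    beta_age2: float = -4e-4
    beta_sex: float = 0.25
    beta_tiv: float = 0.004
    age_mean: float = 32.4
    age_sd: float = 11.9
    tiv_mean: float = 1450.0
    tiv_sd: float = 130.0
    female_fraction: float = 0.40
    waypoints: tuple[float, ...] = (1.0, 2.0, 3.0)
    z_max: float = 5.0
    clinical: ClinicalModel = field(default_factory=ClinicalModel)
    seed: int = 0

    def __post_init__(self) -> None:
        f = np.asarray(self.subtype_fractions, dtype=float)
        if np.any(f < 0) or np.any(f > 1) or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("subtype_fractions must lie in [0,1] and sum to 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.stage_probs is not None:
            p = np.asarray(self.stage_probs, dtype=float)
            if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError("stage_probs must be a probability vector")

    def spec(self, atlas: ROIAtlas = DEFAULT_ATLAS) -> ZScoreEventModelSpec:
        return event_spec_for(atlas, self.waypoints, self.z_max)

    def sequences(self, atlas: ROIAtlas = DEFAULT_ATLAS) -> tuple[EventSequence, ...]:
        if self.planted_sequences is not None:
            return self.planted_sequences
        return default_trajectories(atlas, self.spec(atlas))


# Per-ROI baseline volumes, arbitrary units; control population SD is 1 unit
# per ROI before site effects so planted deviations are exact z-units.
def _roi_baselines(n_roi: int) -> np.ndarray:
    return np.linspace(8.0, 12.0, n_roi)


def control_model_mean(
    config: SimulationConfig,
    age: np.ndarray,
    sex: np.ndarray,
    tiv: np.ndarray,
    atlas: ROIAtlas = DEFAULT_ATLAS,
) -> np.ndarray:
    """Deterministic (pre-site, pre-noise) control mean per subject x ROI."""
    base = _roi_baselines(len(atlas))
    a = np.asarray(age) - config.age_mean
    cov = (
        config.beta_age * a
        + config.beta_age2 * (a**2 - config.age_sd**2)
        + config.beta_sex * np.asarray(sex)
        + config.beta_tiv * (np.asarray(tiv) - config.tiv_mean)
    )
    return base[None, :] + cov[:, None]


def _assign_sites(n: int, n_sites: int, rng: np.random.Generator, label: str) -> np.ndarray:
    if n < 2 * n_sites:
        raise ValueError(
            f"{label}: need at least 2 subjects per site ({n} subjects, {n_sites} sites)"
        )
    sites = np.tile(np.arange(n_sites), n // n_sites + 1)[:n]
    return rng.permutation(sites)


def generate_cohort(
    config: SimulationConfig, atlas: ROIAtlas = DEFAULT_ATLAS
) -> pd.DataFrame:
    """Simulate one cohort table (controls + patients), bit-reproducible
    under a fixed ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    spec = config.spec(atlas)
    seqs = config.sequences(atlas)
    if len(seqs) != len(config.subtype_fractions):
        raise ValueError("one planted sequence per subtype fraction required")
    for s in seqs:
        s.validate(spec)
    E = spec.n_events
    curves = [stage_expectations(s.to_order(spec), spec) for s in seqs]

    rows = []
    for group, n in (("control", config.n_controls), ("patient", config.n_patients)):
        sites = _assign_sites(n, config.n_sites, rng, f"n_{group}s")
        age = np.clip(rng.normal(config.age_mean, config.age_sd, n), 16.0, 70.0)
        sex = (rng.random(n) >= config.female_fraction).astype(int)  # 1 = male
        tiv = rng.normal(config.tiv_mean, config.tiv_sd, n)
        mean = control_model_mean(config, age, sex, tiv, atlas)
        if group == "patient":
            subtype = rng.choice(len(seqs), size=n, p=config.subtype_fractions)
            if config.stage_probs is None:
                stage = rng.integers(0, E + 1, size=n)
            else:
                stage = rng.choice(E + 1, size=n, p=config.stage_probs)
            direction = np.asarray(atlas.loss_direction, dtype=float)
            g = np.stack([curves[c][k] for c, k in zip(subtype, stage)])
            mean = mean - direction[None, :] * g
        else:
            subtype = np.full(n, -1)
            stage = np.full(n, -1)
        vol = mean + rng.normal(0.0, config.noise_sd, size=mean.shape)
        shift = np.asarray(config.site_shifts)[sites % len(config.site_shifts)]
        scale = np.asarray(config.site_scales)[sites % len(config.site_scales)]
        vol = vol * scale[:, None] + shift[:, None]
        df = pd.DataFrame(vol, columns=list(atlas.names))
        df.insert(0, "tiv", tiv)
        df.insert(0, "sex", sex)
        df.insert(0, "age", age)
        df.insert(0, "site", [f"site{s + 1}" for s in sites])
        df.insert(0, "group", group)
        df["true_subtype"] = pd.array(
            np.where(subtype >= 0, subtype, pd.NA), dtype="Int64"
        )
        df["true_stage"] = pd.array(np.where(stage >= 0, stage, pd.NA), dtype="Int64")
        rows.append(df)
    out = pd.concat(rows, ignore_index=True)
    out.insert(0, "subject_id", [f"S{i:05d}" for i in range(len(out))])
    return out


# ---------------------------------------------------------------------------
# Clinical scores
# ---------------------------------------------------------------------------


def _duration_quantile(p: np.ndarray, cm: ClinicalModel) -> np.ndarray:
    """Inverse CDF of the illness-duration marginal: a three-part mixture
    matching the early/middle/late bin occupancy of a mixed first-episode +
    chronic population."""
    w1, w2, w3 = cm.duration_bin_weights
    p = np.clip(p, 1e-12, 1 - 1e-12)
    out = np.empty_like(p)
    early = p < w1
    mid = (~early) & (p < w1 + w2)
    late = ~(early | mid)
    out[early] = 0.08 + (p[early] / w1) * (2.0 - 0.08)
    out[mid] = 2.0 + ((p[mid] - w1) / w2) * 8.0
    q = (p[late] - w1 - w2) / w3
    out[late] = 10.0 + np.minimum(-cm.late_tail_scale * np.log1p(-q), cm.late_tail_cap)
    return out


def generate_clinical(
    cohort: pd.DataFrame,
    config: SimulationConfig,
    atlas: ROIAtlas = DEFAULT_ATLAS,
) -> pd.DataFrame:
    """Add illness duration and PANSS subscale columns for patients.

    Duration is coupled to the true stage through a Gaussian copula at the
    configured rank correlation; subscales follow subtype-specific linear
    duration trends plus Gaussian noise.  Requires simulation truth columns.
    """
    if "true_stage" not in cohort.columns or cohort.loc[
        cohort["group"] == "patient", "true_stage"
    ].isna().any():
        raise ValueError("cohort lacks true_stage; generate_clinical needs simulated truth")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC11]).generate_state(1)[0])
    cm = config.clinical
    out = cohort.copy()
    pat = out["group"] == "patient"
    n = int(pat.sum())
    E = config.spec(atlas).n_events

    stage = out.loc[pat, "true_stage"].to_numpy(dtype=float)
    stage_sd = math.sqrt(((E + 1) ** 2 - 1) / 12.0)
    z_stage = (stage - E / 2.0) / stage_sd
    rho = cm.stage_duration_rho
    u = rho * z_stage + math.sqrt(1 - rho**2) * rng.standard_normal(n)
    duration = _duration_quantile(norm.cdf(u), cm)

    subtype = out.loc[pat, "true_subtype"].to_numpy(dtype=int)
    out.loc[pat, "illness_duration"] = duration
    total = np.zeros(n)
    for name, (base, slopes, noise_sd) in cm.subscales.items():
        slope = np.asarray(slopes, dtype=float)[subtype]
        vals = base + slope * duration + rng.normal(0.0, noise_sd, n)
        out.loc[pat, name] = vals
        if name in ("panss_positive", "panss_negative", "panss_general"):
            total += vals
    out.loc[pat, "panss_total"] = total
    return out


# ---------------------------------------------------------------------------
# I/O and truth-column hygiene
# ---------------------------------------------------------------------------


def feature_matrix(cohort: pd.DataFrame, atlas: ROIAtlas = DEFAULT_ATLAS) -> pd.DataFrame:
    """ROI columns only, in atlas order — the sole view inference stages see.

    Acts as the column whitelist: simulation-truth columns cannot leak into
    any downstream computation that goes through this accessor.
    """
    return cohort.loc[:, list(atlas.names)].copy()


_COLUMN_DOC = {
    "subject_id": "unique subject identifier",
    "group": "patient or control",
    "site": "acquisition site (batch) label",
    "age": "age in years",
    "sex": "0 = female, 1 = male",
    "tiv": "total intracranial volume, arbitrary units",
    "true_subtype": "simulation truth: planted subtype index (hidden from inference)",
    "true_stage": "simulation truth: planted stage 0..E (hidden from inference)",
    "illness_duration": "years since illness onset",
    "panss_total": "sum of positive, negative and general subscales",
}


def write_cohort(cohort: pd.DataFrame, path: "str | Path") -> Path:
    """Write a cohort as TSV with a sidecar JSON column dictionary."""
    path = Path(path)
    cohort.to_csv(path, sep="\t", index=False)
    doc = {}
    for col in cohort.columns:
        if col in _COLUMN_DOC:
            doc[col] = _COLUMN_DOC[col]
        elif col.startswith("panss_"):
            doc[col] = "PANSS subscale score (latent continuous severity)"
        else:
            doc[col] = "gray-matter volume, arbitrary units"
    sidecar = path.with_suffix(path.suffix + ".columns.json")
    sidecar.write_text(json.dumps(doc, indent=2))
    return path


def read_cohort(path: "str | Path") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in TRUTH_COLUMNS:
        if col in df.columns:
            df[col] = df[col].astype("Int64")
    return df
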