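"""Seeded generators for every input shape the pipeline consumes.

Each generator emits its ground truth (planted differentially expressed
genes, planted activity ordering, pre-bias log-ratios) alongside the data
so that downstream recovery can be tested against a known answer.

The defaults mirror the study design being emulated: an 11-array
knockdown experiment (5 vs 6 two-channel arrays), a tumor cohort over the
five intrinsic breast-cancer subtypes with exponential survival tied to a
marker gene, and a four-population sorted mammary-lineage panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SUBTYPES",
    "LINEAGES",
    "KnockdownSimSpec",
    "CohortSimSpec",
    "LineageSimSpec",
    "simulate_knockdown",
    "simulate_cohort",
    "simulate_lineages",
    "simulate_two_channel",
]

SUBTYPES = ("LumA", "LumB", "HER2", "Basal", "Claudin-low")
LINEAGES = ("MaSC", "LP", "ML", "St")


def _check_seed(seed: int) -> int:
    if seed is None or int(seed) < 0:
        raise ValueError("seed must be a non-negative integer")
    return int(seed)


def _gene_sd(rng, n_genes, sigma) -> np.ndarray:
    """Per-gene noise SD: scalar -> homoscedastic; (low, high) -> draw.

    Heteroscedastic SDs come from a scaled inverse-chi-square variance
    draw (4 df, right-skewed, inverse-gamma family) clipped to the stated
    range, so low-variance genes exist and the SAM fudge factor s0 has
    something to regularize.
    """
    if np.isscalar(sigma):
        if sigma < 0:
            raise ValueError("sigma must be non-negative")
        return np.full(n_genes, float(sigma))
    low, high = float(sigma[0]), float(sigma[1])
    if not 0 <= low <= high:
        raise ValueError("sigma range must satisfy 0 <= low <= high")
    df = 4.0
    mid2 = ((low + high) / 2.0) ** 2
    var = mid2 * df / rng.chisquare(df, size=n_genes)
    return np.clip(np.sqrt(var), low, high)


@dataclass(frozen=True)
class KnockdownSimSpec:
    """Two-class knockdown experiment with a planted DE fraction."""

    n_genes: int = 1000
    n_class1: int = 5   # knockdown replicates
    n_class2: int = 6   # control replicates
    de_fraction: float = 0.10
    effect_size: float = 2.0     # log2 mean shift of planted genes
    sigma: float | tuple[float, float] = 0.5
    missing_rate: float = 0.0
    two_sided: bool = True       # alternate +/- planted shifts
    seed: int = 0


def simulate_knockdown(
    spec: KnockdownSimSpec,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Simulate a two-class log2 expression matrix with planted DE genes.

    Returns
    -------
    matrix : DataFrame, genes x samples, NaN for missing values.
    labels : Series mapping sample id -> class label
        ("knockdown" for class 1, "control" for class 2).
    truth : DataFrame indexed by the planted gene ids with column
        ``shift`` (the signed log2 mean shift added to class 1).
    """
    if spec.n_class1 < 2 or spec.n_class2 < 2:
        raise ValueError("need at least 2 samples per class")
    if spec.n_genes <= 0:
        raise ValueError("n_genes must be positive")
    if not 0 <= spec.de_fraction <= 1:
        raise ValueError("de_fraction must be in [0, 1]")
    if not 0 <= spec.missing_rate < 1:
        raise ValueError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(_check_seed(spec.seed))

    n = spec.n_class1 + spec.n_class2
    genes = np.array([f"G{i:05d}" for i in range(spec.n_genes)])
    samples = [f"KD{i+1}" for i in range(spec.n_class1)] + [
        f"CTL{i+1}" for i in range(spec.n_class2)
    ]
    labels = pd.Series(
        ["knockdown"] * spec.n_class1 + ["control"] * spec.n_class2,
        index=samples,
        name="class",
    )

    n_de = int(round(spec.de_fraction * spec.n_genes))
    de_idx = rng.choice(spec.n_genes, size=n_de, replace=False)
    de_idx.sort()
    if spec.two_sided:
        signs = np.where(np.arange(n_de) % 2 == 0, 1.0, -1.0)
    else:
        signs = np.ones(n_de)
    shifts = signs * spec.effect_size

    sd = _gene_sd(rng, spec.n_genes, spec.sigma)
    baseline = rng.normal(8.0, 1.0, size=spec.n_genes)
    x = baseline[:, None] + rng.normal(size=(spec.n_genes, n)) * sd[:, None]
    x[de_idx, : spec.n_class1] += shifts[:, None]

    if spec.missing_rate > 0:
        mask = rng.random(size=x.shape) < spec.missing_rate
        x[mask] = np.nan

    matrix = pd.DataFrame(x, index=genes, columns=samples)
    truth = pd.DataFrame({"shift": shifts}, index=genes[de_idx])
    return matrix, labels, truth


@dataclass(frozen=True)
class CohortSimSpec:
    """Tumor cohort: subtype-shifted genes + marker-linked exponential survival."""

    n_per_subtype: int | Mapping[str, int] = 30
    n_genes: int = 200
    signature_genes: int = 50
    subtype_shift: Mapping[str, float] = field(
        default_factory=lambda: {
            "LumA": 1.0, "LumB": 0.7, "HER2": 0.2, "Basal": -1.0, "Claudin-low": -0.7,
        }
    )
    marker_gene: str = "MYB"
    baseline_hazard: float = 0.05   # events per time unit
    log_hazard_ratio: float = 0.0   # per log2 unit of marker expression
    dichotomize_hazard: bool = False  # hazard acts on the above/below-median indicator
    censor_rate: float = 0.0
    sigma: float = 0.5
    seed: int = 0


def simulate_cohort(spec: CohortSimSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a tumor expression matrix and clinical table.

    The first ``signature_genes`` genes are shifted per subtype by
    ``subtype_shift``. One extra row, ``marker_gene``, drives the hazard:
    each sample's survival time is exponential with rate
    ``baseline_hazard * exp(log_hazard_ratio * marker expression)``
    (marker centered; with ``dichotomize_hazard`` the covariate is the
    above/below-median indicator, so exp(log_hazard_ratio) is exactly
    the hazard ratio between the halves). Censoring is an independent
    exponential clock
    calibrated so that a baseline-hazard subject is censored with
    probability ``censor_rate``.

    Returns (matrix, clinical) where clinical has columns
    subtype, os_time, os_event, size, grade, pcr indexed by sample id.
    """
    if spec.baseline_hazard <= 0:
        raise ValueError("baseline_hazard must be positive")
    if not 0 <= spec.censor_rate < 1:
        raise ValueError("censor_rate must be in [0, 1)")
    if isinstance(spec.n_per_subtype, Mapping):
        counts = {s: int(spec.n_per_subtype.get(s, 0)) for s in SUBTYPES}
    else:
        counts = {s: int(spec.n_per_subtype) for s in SUBTYPES}
    if any(c <= 0 for c in counts.values()):
        raise ValueError("every subtype group must be non-empty")
    if spec.signature_genes > spec.n_genes:
        raise ValueError("signature_genes cannot exceed n_genes")
    rng = np.random.default_rng(_check_seed(spec.seed))

    subtype = np.repeat(list(counts), list(counts.values()))
    n = len(subtype)
    samples = [f"T{i+1:04d}" for i in range(n)]
    shifts = np.array([spec.subtype_shift.get(s, 0.0) for s in subtype])

    genes = [f"SG{i:04d}" for i in range(spec.signature_genes)] + [
        f"BG{i:04d}" for i in range(spec.n_genes - spec.signature_genes)
    ]
    x = rng.normal(size=(spec.n_genes, n)) * spec.sigma
    x[: spec.signature_genes, :] += shifts[None, :]

    marker = shifts + rng.normal(size=n) * spec.sigma
    matrix = pd.DataFrame(
        np.vstack([marker, x]),
        index=[spec.marker_gene] + genes,
        columns=samples,
    )

    if spec.dichotomize_hazard:
        covariate = (marker >= np.median(marker)).astype(float)
    else:
        covariate = marker - marker.mean()
    hazard = spec.baseline_hazard * np.exp(spec.log_hazard_ratio * covariate)
    t_event = rng.exponential(1.0 / hazard)
    if spec.censor_rate > 0:
        lam_c = spec.baseline_hazard * spec.censor_rate / (1.0 - spec.censor_rate)
        t_cens = rng.exponential(1.0 / lam_c, size=n)
        os_time = np.minimum(t_event, t_cens)
        os_event = t_event <= t_cens
    else:
        os_time, os_event = t_event, np.ones(n, dtype=bool)

    clinical = pd.DataFrame(
        {
            "subtype": subtype,
            "os_time": os_time,
            "os_event": os_event,
            "size": rng.choice(["T1", "T2", "T3"], size=n),
            "grade": rng.choice([1, 2, 3], size=n),
            "pcr": rng.random(n) < 0.2,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return matrix, clinical


@dataclass(frozen=True)
class LineageSimSpec:
    """Sorted-lineage panel with a planted signature-activity ordering."""

    weights: pd.Series = None  # signature weights (index = gene ids); required
    n_per_population: int = 6
    n_background: int = 100
    activity_levels: Mapping[str, float] = field(
        default_factory=lambda: {"ML": 1.0, "LP": 0.5, "MaSC": 0.25, "St": 0.0}
    )
    shift: float = 1.0      # log2 scale factor applied to activity_levels
    sigma: float = 0.5
    seed: int = 0

    def ordering(self) -> list[str]:
        """Planted populations ordered by decreasing activity."""
        return sorted(self.activity_levels, key=self.activity_levels.get, reverse=True)


def simulate_lineages(spec: LineageSimSpec) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate a four-population panel expressing a signature at planted levels.

    For each population p, signature genes are shifted by
    ``shift * activity_levels[p] * sign(weight)`` so that projecting the
    signature recovers the planted activity ordering.

    Returns (matrix, populations) with populations a Series mapping
    sample id -> population label.
    """
    if spec.weights is None or len(spec.weights) == 0:
        raise ValueError("spec.weights (signature weights) is required")
    if spec.n_per_population < 2:
        raise ValueError("need at least 2 samples per population")
    if set(spec.activity_levels) != set(LINEAGES):
        raise ValueError(f"activity_levels must cover exactly {LINEAGES}")
    rng = np.random.default_rng(_check_seed(spec.seed))

    w = spec.weights.astype(float)
    pops = np.repeat(LINEAGES, spec.n_per_population)
    n = len(pops)
    samples = [f"{p}{i+1}" for p in LINEAGES for i in range(spec.n_per_population)]
    levels = np.array([spec.activity_levels[p] for p in pops])

    sig = np.sign(w.to_numpy())[:, None] * (spec.shift * levels)[None, :]
    sig = sig + rng.normal(size=sig.shape) * spec.sigma
    bg_genes = [f"NG{i:04d}" for i in range(spec.n_background)]
    bg = rng.normal(size=(spec.n_background, n)) * spec.sigma

    matrix = pd.DataFrame(
        np.vstack([sig, bg]),
        index=list(w.index) + bg_genes,
        columns=samples,
    )
    populations = pd.Series(pops, index=samples, name="population")
    return matrix, populations


def simulate_two_channel(
    n_spots: int,
    bias_fn: Callable[[np.ndarray], np.ndarray] | None = None,
    seed: int = 0,
    noise_sd: float = 0.05,
    a_range: tuple[float, float] = (6.0, 14.0),
    m_sd: float = 0.5,
) -> pd.DataFrame:
    """Simulate a two-channel spot table with intensity-dependent dye bias.

    ``bias_fn`` maps mean log-intensity A to a log-ratio offset; the
    observed log-ratio is M_true + bias_fn(A) + noise. The pre-bias
    ``m_true`` column is retained for oracle comparisons.

    Returns DataFrame with columns probe_id, cy3, cy5, a, m_true, m_obs.
    """
    if n_spots < 1:
        raise ValueError("n_spots must be positive")
    rng = np.random.default_rng(_check_seed(seed))
    a = rng.uniform(*a_range, size=n_spots)
    m_true = rng.normal(0.0, m_sd, size=n_spots)
    bias = np.zeros(n_spots) if bias_fn is None else np.asarray(bias_fn(a), float)
    m_obs = m_true + bias + rng.normal(0.0, noise_sd, size=n_spots)
    return pd.DataFrame(
        {
            "probe_id": [f"P{i:06d}" for i in range(n_spots)],
            "cy3": 2.0 ** (a - m_obs / 2.0),
            "cy5": 2.0 ** (a + m_obs / 2.0),
            "a": a,
            "m_true": m_true,
            "m_obs": m_obs,
        }
    )
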