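"""Seeded generator of multi-platform cohorts with known ground truth.

The generator emulates the structure of a merged multi-study microarray
cohort: several platforms with per-gene additive (gamma) and multiplicative
(delta) batch effects on the log2 scale, three clinical groups placed on a
latent severity continuum in [0, 1], planted gene modules whose expression
moves linearly with severity (a hemostasis-like module up, a T-cell-like
module down), stable housekeeping genes, and — separately — bulk profiles
mixed from a known cell-type signature matrix.

Severity is sampled as Beta(1, 8) for controls, Uniform(0, 1) for
bacteremia (deliberately spanning the continuum) and Beta(8, 1) for septic
shock, so bacteremia samples spread across the trajectory while the group
means stay strictly ordered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .deconv import SignatureMatrixRef
from .io import ExpressionMatrix, Group, MergedCohort, SampleMetadata

__all__ = [
    "ModuleEffect",
    "SynthConfig",
    "SyntheticTruth",
    "default_config",
    "generate_cohort",
    "generate_signature_matrix",
    "generate_mixtures",
]


@dataclass(frozen=True)
class ModuleEffect:
    """A planted gene module: expression shifts by slope * severity (log2)."""

    genes: tuple[str, ...]
    slope: float  # signed, log2 units per unit severity


@dataclass
class SynthConfig:
    n_platforms: int = 5
    n_controls: int = 50  # per platform
    n_bacteremia: int = 50
    n_shock: int = 10
    n_genes: int = 2000
    batch_gamma: tuple[float, ...] = (0.0, 1.5, -1.5, 1.0, -1.2)
    batch_delta: tuple[float, ...] = (1.0, 2.0, 0.7, 1.5, 1.2)
    severity_effects: dict[str, ModuleEffect] = field(default_factory=dict)
    housekeeping_genes: tuple[str, ...] = ()
    noise_sd: float = 0.3
    baseline_range: tuple[float, float] = (4.0, 12.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_controls, self.n_bacteremia, self.n_shock) < 0:
            raise ValueError("sample counts must be nonnegative")
        if len(self.batch_gamma) != self.n_platforms or len(self.batch_delta) != self.n_platforms:
            raise ValueError("one batch gamma/delta per platform required")
        if any(d <= 0 for d in self.batch_delta):
            raise ValueError("batch delta must be positive")
        module_genes = {g for eff in self.severity_effects.values() for g in eff.genes}
        if module_genes & set(self.housekeeping_genes):
            raise ValueError("severity modules must be disjoint from housekeeping panel")
        universe = set(gene_names(self.n_genes))
        bad = (module_genes | set(self.housekeeping_genes)) - universe
        if bad:
            raise ValueError(f"genes outside the 1..n_genes universe: {sorted(bad)[:5]}")

    @property
    def gene_ids(self) -> list[str]:
        return gene_names(self.n_genes)


def gene_names(n_genes: int) -> list[str]:
    width = max(4, len(str(n_genes)))
    return [f"G{i:0{width}d}" for i in range(1, n_genes + 1)]


def default_config(seed: int = 0) -> SynthConfig:
    """Study-shaped default: 5 platforms x (50 controls, 50 bacteremia,
    10 septic shock), 2000 genes, 10 housekeeping genes, a 40-gene
    hemostasis-like module rising with severity and a 24-gene T-cell-like
    module falling with it."""
    genes = gene_names(2000)
    housekeeping = tuple(genes[0:10])
    hemostasis = tuple(genes[10:50])
    tcell = tuple(genes[50:74])
    effects = {
        "hemostasis_up": ModuleEffect(hemostasis, +2.5),
        "tcell_down": ModuleEffect(tcell, -2.0),
    }
    return SynthConfig(
        severity_effects=effects,
        housekeeping_genes=housekeeping,
        seed=seed,
    )


@dataclass
class SyntheticTruth:
    """Everything the generator knows that the pipeline must recover."""

    latent_severity: pd.Series  # per sample, in [0, 1]
    true_de_genes: dict[str, list[tuple[str, float]]]  # contrast -> (gene, slope)
    true_batch: tuple[np.ndarray, np.ndarray]  # (gamma, delta), per platform
    modules: dict[str, ModuleEffect] = field(default_factory=dict)
    housekeeping_genes: tuple[str, ...] = ()
    true_fractions: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.true_fractions is not None:
            rowsum = self.true_fractions.sum(axis=1).to_numpy()
            if (self.true_fractions.to_numpy() < 0).any():
                raise ValueError("mixture fractions must be nonnegative")
            if np.abs(rowsum - 1.0).max() > 1e-9:
                raise ValueError("mixture fraction rows must sum to 1")


_SEVERITY_PARAMS = {
    Group.HEALTHY_CONTROL: ("beta", 1.0, 8.0),
    Group.BACTEREMIA: ("uniform", 0.0, 1.0),
    Group.SEPTIC_SHOCK: ("beta", 8.0, 1.0),
}


def _severity_grid(group: Group, n: int) -> np.ndarray:
    """Deterministic severity values: the (i+0.5)/n quantiles of the group's
    severity distribution, so the continuum is covered systematically and
    the generator's randomness is confined to noise."""
    from scipy import stats as sps

    q = (np.arange(n) + 0.5) / n if n else np.empty(0)
    kind, a, b = _SEVERITY_PARAMS[group]
    if kind == "beta":
        return sps.beta.ppf(q, a, b)
    return a + q * (b - a)


def generate_cohort(cfg: SynthConfig | None = None) -> tuple[MergedCohort, SyntheticTruth]:
    """Simulate a merged multi-platform cohort.

    Per sample on platform p:
    ``value = baseline_g + slope_g * severity + gamma[p] + N(0, noise_sd) * delta[p]``
    with the baseline drawn once and shared across platforms, the severity
    term applied only to module genes, and housekeeping genes carrying no
    severity term.  Same seed, same output.
    """
    if cfg is None:
        cfg = default_config()
    rng = np.random.default_rng(cfg.seed)
    genes = cfg.gene_ids
    n_genes = len(genes)
    baseline = rng.uniform(*cfg.baseline_range, size=n_genes)

    slope = np.zeros(n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for eff in cfg.severity_effects.values():
        for g in eff.genes:
            slope[gene_pos[g]] = eff.slope

    columns: dict[str, np.ndarray] = {}
    meta: list[SampleMetadata] = []
    severities: dict[str, float] = {}
    counts = [
        (Group.HEALTHY_CONTROL, cfg.n_controls),
        (Group.BACTEREMIA, cfg.n_bacteremia),
        (Group.SEPTIC_SHOCK, cfg.n_shock),
    ]
    # one severity value per (group, within-platform index), shared across
    # platforms, so that platforms with identical group design differ only
    # through their batch terms and noise
    group_sev = {group: _severity_grid(group, n) for group, n in counts}
    for p in range(cfg.n_platforms):
        gamma = cfg.batch_gamma[p]
        delta = cfg.batch_delta[p]
        platform_id = f"PL{p + 1}"
        dataset_id = f"DS{p + 1}"
        for group, n in counts:
            sev = group_sev[group]
            ages = rng.uniform(0, 180, size=n)
            for i in range(n):
                sid = f"{platform_id}_{group.value}_{i + 1:03d}"
                noise = rng.normal(0.0, cfg.noise_sd, size=n_genes)
                columns[sid] = baseline + slope * sev[i] + gamma + noise * delta
                sex = rng.choice(["M", "F"]) if p < 3 else None
                meta.append(
                    SampleMetadata(sid, dataset_id, platform_id, group, float(ages[i]), sex)
                )
                severities[sid] = float(sev[i])

    values = pd.DataFrame(columns, index=genes)
    cohort = MergedCohort(
        expr=ExpressionMatrix(values),
        meta=meta,
        provenance={f"DS{p + 1}": sum(n for _, n in counts) for p in range(cfg.n_platforms)},
    )
    de_lists = {
        "case_vs_control": [
            (g, eff.slope) for eff in cfg.severity_effects.values() for g in eff.genes
        ]
    }
    truth = SyntheticTruth(
        latent_severity=pd.Series(severities),
        true_de_genes=de_lists,
        true_batch=(np.asarray(cfg.batch_gamma), np.asarray(cfg.batch_delta)),
        modules=dict(cfg.severity_effects),
        housekeeping_genes=cfg.housekeeping_genes,
    )
    return cohort, truth


def generate_signature_matrix(
    n_types: int,
    markers_per_type: int,
    fold: float = 10.0,
    seed: int = 0,
    n_genes: int | None = None,
    base_range: tuple[float, float] = (5.0, 15.0),
) -> SignatureMatrixRef:
    """Build a marker-structured linear-scale cell-type signature.

    Each type gets ``markers_per_type`` exclusive marker genes whose
    expression is ``fold`` times the shared baseline; all other genes share
    the baseline across types.  As fold -> 1 the columns become collinear
    and the condition number diverges.
    """
    if n_types < 2:
        raise ValueError("need at least two cell types")
    if fold <= 1:
        raise ValueError("fold must exceed 1")
    needed = n_types * markers_per_type
    if n_genes is None:
        n_genes = needed
    if needed > n_genes:
        raise ValueError(f"{needed} marker genes required but only {n_genes} genes available")
    rng = np.random.default_rng(seed)
    genes = [f"M{i:04d}" for i in range(1, n_genes + 1)]
    base = rng.uniform(*base_range, size=n_genes)
    values = np.tile(base[:, None], (1, n_types))
    for t in range(n_types):
        rows = slice(t * markers_per_type, (t + 1) * markers_per_type)
        values[rows, t] *= fold
    df = pd.DataFrame(values, index=genes, columns=[f"type_{t + 1}" for t in range(n_types)])
    return SignatureMatrixRef(df)


def generate_mixtures(
    sig: SignatureMatrixRef,
    fractions: pd.DataFrame,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Mix bulk profiles from the signature at known proportions.

    Linear-scale profile = fractions @ signature^T, perturbed by
    multiplicative log-normal noise of scale ``noise_sd`` (log2 units), then
    stored as log2(x + 1).
    """
    frac = fractions.to_numpy(dtype=float)
    if (frac < 0).any():
        raise ValueError("fractions must be nonnegative")
    if np.abs(frac.sum(axis=1) - 1.0).max() > 1e-6:
        raise ValueError("each fraction row must sum to 1 within 1e-6")
    if list(fractions.columns) != sig.cell_types:
        raise ValueError("fraction columns must match signature cell types")
    rng = np.random.default_rng(seed)
    linear = frac @ sig.values.to_numpy(dtype=float).T  # samples x genes
    if noise_sd > 0:
        linear = linear * np.exp2(rng.normal(0.0, noise_sd, size=linear.shape))
    values = pd.DataFrame(
        np.log2(linear + 1.0).T, index=sig.genes, columns=fractions.index.astype(str)
    )
    expr = ExpressionMatrix(values)
    truth = SyntheticTruth(
        latent_severity=pd.Series(dtype=float),
        true_de_genes={},
        true_batch=(np.zeros(0), np.ones(0)),
        true_fractions=fractions.copy(),
    )
    return expr, truth
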