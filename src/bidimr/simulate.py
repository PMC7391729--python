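"""Synthetic two-sample GWAS summary statistics with known ground truth.

Structural model: per-SNP genotypes G ~ Binomial(2, maf) in two
non-overlapping samples; exposure X = Σ γⱼGⱼ + c_x·U + ε_x; outcome
Y = θ·X + Σ αⱼGⱼ + c_y·U + ε_y, with U and ε standard normal and noise
variances chosen so X and Y have unit variance in expectation.  Summary
statistics are per-SNP marginal simple regressions, computed in the
exposure sample for X and independently in the outcome sample for Y.

Two modes:
  * ``individual`` — genotypes are actually drawn, so beta/se/p/eaf and
    realized LD are mutually coherent (supports LD blocks);
  * ``asymptotic`` — effect estimates are drawn straight from their
    normal sampling distributions (fast; independent SNPs only), for
    large-replicate property and calibration tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .sumstats import LdTable, SnpRecord, SummaryStatsTable

_MIN_P = 1e-300  # keep pvalue inside (0, 1]

_NONPALINDROMIC_PAIRS = (
    ("A", "C"), ("C", "A"), ("A", "G"), ("G", "A"),
    ("C", "T"), ("T", "C"), ("G", "T"), ("T", "G"),
)
_PALINDROMIC_PAIRS = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))


class SimulationConfigError(ValueError):
    """Infeasible or invalid generative-model configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for one exposure→outcome two-sample dataset."""

    m: int
    n_exposure: int
    n_outcome: int
    h2x: float
    theta: float
    seed: int
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_causal: int | None = None
    gamma: tuple[float, ...] | None = None  # explicit per-SNP exposure effects
    alpha: tuple[float, ...] | None = None  # explicit per-SNP direct outcome effects
    pleio_frac: float = 0.0
    pleio_mean: float = 0.0
    pleio_sd: float = 0.0
    confounder_x: float = 0.0
    confounder_y: float = 0.0
    n_outliers: int = 0
    outlier_shift: float = 6.0  # ratio-scale shift in units of sy/|gamma|
    ld_blocks: tuple[tuple[int, float], ...] | None = None
    outcome_seed: int | None = None
    swap_frac: float = 0.0  # outcome rows reported with effect/other swapped
    strand_flip_frac: float = 0.0  # outcome rows reported on the other strand
    palindromic_frac: float = 0.0  # SNPs assigned A/T or G/C allele pairs
    rsid_prefix: str = "rs"
    exposure_trait: str = "exposure"
    outcome_trait: str = "outcome"
    exposure_source: str = "sim_exposure"
    outcome_source: str = "sim_outcome"

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise SimulationConfigError(f"maf_range must be within (0, 0.5], got {self.maf_range}")
        if not (0 <= self.h2x < 1):
            raise SimulationConfigError(f"h2x must be in [0, 1), got {self.h2x}")
        if not (0 <= self.pleio_frac <= 1):
            raise SimulationConfigError(f"pleio_frac must be in [0, 1], got {self.pleio_frac}")
        if self.m <= 0 or self.n_exposure < 10 or self.n_outcome < 10:
            raise SimulationConfigError("m must be positive and sample sizes >= 10")
        if self.seed is None:
            raise SimulationConfigError("seed is mandatory")
        if self.gamma is not None and len(self.gamma) != self.m:
            raise SimulationConfigError("explicit gamma must have length m")
        if self.alpha is not None and len(self.alpha) != self.m:
            raise SimulationConfigError("explicit alpha must have length m")
        n_causal = self.m if self.n_causal is None else self.n_causal
        if not (0 <= n_causal <= self.m):
            raise SimulationConfigError("n_causal must be in [0, m]")
        if self.n_outliers > n_causal:
            raise SimulationConfigError("n_outliers cannot exceed the causal SNP count")
        if self.h2x + self.confounder_x**2 >= 1:
            raise SimulationConfigError(
                "infeasible exposure variance budget: h2x + confounder_x^2 >= 1"
            )
        if self.ld_blocks:
            if sum(size for size, _ in self.ld_blocks) > self.m:
                raise SimulationConfigError("LD blocks cover more SNPs than m")
            for size, r in self.ld_blocks:
                if size < 2 or not (0 <= r < 1):
                    raise SimulationConfigError("each LD block needs size >= 2 and r in [0, 1)")


@dataclass(frozen=True)
class TrueParams:
    """Ground truth emitted with every simulated dataset (tests only)."""

    theta: float
    gamma: np.ndarray
    alpha: np.ndarray
    mafs: np.ndarray
    rsids: tuple[str, ...]
    causal_ids: tuple[str, ...]
    outlier_ids: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "theta": self.theta,
            "gamma": self.gamma.tolist(),
            "alpha": self.alpha.tolist(),
            "mafs": self.mafs.tolist(),
            "rsids": list(self.rsids),
            "causal_ids": list(self.causal_ids),
            "outlier_ids": list(self.outlier_ids),
        }


def _streams(config: SimConfig) -> dict[str, np.random.Generator]:
    """Independent seeded streams; the outcome stream has its own seed knob."""
    out_seed = config.seed if config.outcome_seed is None else config.outcome_seed
    return {
        "params": np.random.default_rng(np.random.SeedSequence([config.seed, 0])),
        "exposure": np.random.default_rng(np.random.SeedSequence([config.seed, 1])),
        "outcome": np.random.default_rng(np.random.SeedSequence([out_seed, 2])),
        "alleles": np.random.default_rng(np.random.SeedSequence([config.seed, 3])),
    }


def _draw_effects(config: SimConfig, rng: np.random.Generator) -> tuple[np.ndarray, ...]:
    m = config.m
    mafs = rng.uniform(*config.maf_range, size=m)
    var_g = 2.0 * mafs * (1.0 - mafs)
    n_causal = m if config.n_causal is None else config.n_causal

    if config.gamma is not None:
        gamma = np.asarray(config.gamma, dtype=float)
    else:
        gamma = np.zeros(m)
        if n_causal > 0 and config.h2x > 0:
            raw = rng.normal(size=n_causal)
            raw = np.where(raw == 0, 1.0, raw)
            scale = np.sqrt(config.h2x / np.sum(var_g[:n_causal] * raw**2))
            gamma[:n_causal] = raw * scale

    if config.alpha is not None:
        alpha = np.asarray(config.alpha, dtype=float)
    else:
        alpha = np.zeros(m)
    n_pleio = int(round(config.pleio_frac * m))
    if n_pleio > 0 and (config.pleio_sd > 0 or config.pleio_mean != 0):
        pleio_idx = rng.choice(m, size=n_pleio, replace=False)
        draws = rng.normal(config.pleio_mean, config.pleio_sd, size=n_pleio)
        # directional pleiotropy is defined in the exposure-increasing
        # orientation; align the direct effect with the sign of gamma so a
        # non-zero mean survives the estimators' bx >= 0 re-orientation
        orientation = np.where(gamma[pleio_idx] < 0, -1.0, 1.0)
        alpha[pleio_idx] = draws * orientation
    if config.n_outliers > 0:
        causal_idx = np.flatnonzero(gamma != 0)
        outlier_idx = causal_idx[-config.n_outliers :]
        se_y = 1.0 / np.sqrt(config.n_outcome * var_g[outlier_idx])
        signs = np.where(rng.random(config.n_outliers) < 0.5, -1.0, 1.0)
        # shift each outlier's ratio by outlier_shift residual SDs
        alpha[outlier_idx] = signs * config.outlier_shift * se_y
    else:
        outlier_idx = np.array([], dtype=int)
    return mafs, gamma, alpha, outlier_idx


def _noise_vars(config: SimConfig, mafs, gamma, alpha) -> tuple[float, float]:
    var_g = 2.0 * mafs * (1.0 - mafs)
    h2x_eff = float(np.sum(var_g * gamma**2))
    var_ex = 1.0 - h2x_eff - config.confounder_x**2
    if var_ex <= 0:
        raise SimulationConfigError("exposure noise variance non-positive")
    var_alpha = float(np.sum(var_g * alpha**2))
    var_ey = (
        1.0
        - config.theta**2
        - var_alpha
        - config.confounder_y**2
        - 2.0 * config.theta * config.confounder_x * config.confounder_y
    )
    if var_ey <= 0:
        raise SimulationConfigError("outcome noise variance non-positive")
    return var_ex, var_ey


def _genotypes(
    rng: np.random.Generator, n: int, mafs: np.ndarray, ld_blocks
) -> np.ndarray:
    """n×m genotype matrix; equicorrelated latent liability within LD blocks."""
    m = len(mafs)
    thresholds = sps.norm.ppf(1.0 - mafs)
    block_of = np.full(m, -1)
    block_r = []
    start = 0
    if ld_blocks:
        for b, (size, r) in enumerate(ld_blocks):
            block_of[start : start + size] = b
            block_r.append(r)
            start += size
    g = np.empty((n, m), dtype=np.float32)
    for hap in range(2):
        z = rng.standard_normal((n, m))
        if ld_blocks:
            for b, r in enumerate(block_r):
                idx = np.flatnonzero(block_of == b)
                shared = rng.standard_normal((n, 1))
                z[:, idx] = np.sqrt(r) * shared + np.sqrt(1.0 - r) * z[:, idx]
        alleles = (z > thresholds).astype(np.float32)
        if hap == 0:
            g = alleles
        else:
            g += alleles
    return g


def _marginal_stats(g: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, ...]:
    """Per-SNP simple-regression beta, se, p and allele frequency."""
    n = len(y)
    g = np.asarray(g, dtype=np.float64)
    gc = g - g.mean(axis=0)
    yc = y - y.mean()
    sxx = np.sum(gc**2, axis=0)
    if np.any(sxx == 0):
        raise SimulationConfigError("monomorphic SNP in sample; increase n or maf range")
    sxy = gc.T @ yc
    syy = float(np.sum(yc**2))
    beta = sxy / sxx
    sse = np.maximum(syy - beta**2 * sxx, 1e-12)
    se = np.sqrt(sse / ((n - 2) * sxx))
    pvals = np.maximum(2.0 * sps.norm.sf(np.abs(beta) / se), _MIN_P)
    eaf = g.mean(axis=0) / 2.0
    return beta, se, pvals, eaf


def _asymptotic_stats(
    rng: np.random.Generator, mu: np.ndarray, mafs: np.ndarray, n: int
) -> tuple[np.ndarray, ...]:
    se = 1.0 / np.sqrt(n * 2.0 * mafs * (1.0 - mafs))
    beta = rng.normal(mu, se)
    pvals = np.maximum(2.0 * sps.norm.sf(np.abs(beta) / se), _MIN_P)
    return beta, se, pvals, mafs.copy()


def _assign_alleles(
    config: SimConfig, rng: np.random.Generator
) -> tuple[list[tuple[str, str]], np.ndarray, np.ndarray]:
    pairs = []
    for _ in range(config.m):
        if rng.random() < config.palindromic_frac:
            pairs.append(_PALINDROMIC_PAIRS[rng.integers(len(_PALINDROMIC_PAIRS))])
        else:
            pairs.append(_NONPALINDROMIC_PAIRS[rng.integers(len(_NONPALINDROMIC_PAIRS))])
    swap = rng.random(config.m) < config.swap_frac
    flip = rng.random(config.m) < config.strand_flip_frac
    return pairs, swap, flip


def _build_table(
    trait: str,
    source: str,
    rsids: Sequence[str],
    pairs: Sequence[tuple[str, str]],
    beta: np.ndarray,
    se: np.ndarray,
    pvals: np.ndarray,
    eaf: np.ndarray,
    n: int,
    swap: np.ndarray | None = None,
    flip: np.ndarray | None = None,
) -> SummaryStatsTable:
    complement = {"A": "T", "T": "A", "C": "G", "G": "C"}
    records = []
    for j, rsid in enumerate(rsids):
        ea, oa = pairs[j]
        b, f = float(beta[j]), float(eaf[j])
        if swap is not None and swap[j]:
            ea, oa = oa, ea
            b, f = -b, 1.0 - f
        if flip is not None and flip[j]:
            ea, oa = complement[ea], complement[oa]
        f = min(max(f, 1e-6), 1.0 - 1e-6)
        records.append(
            SnpRecord(
                rsid=rsid,
                effect_allele=ea,
                other_allele=oa,
                beta=b,
                se=float(se[j]),
                pvalue=float(pvals[j]),
                eaf=f,
                n=n,
            )
        )
    return SummaryStatsTable(trait_id=trait, source_id=source, records=tuple(records))


def _realized_ld(g: np.ndarray, rsids: Sequence[str], min_r2: float = 0.01) -> LdTable:
    corr = np.corrcoef(np.asarray(g, dtype=np.float64), rowvar=False)
    r2 = corr**2
    table = LdTable()
    m = len(rsids)
    for i in range(m):
        for j in range(i + 1, m):
            if r2[i, j] >= min_r2:
                table.add(rsids[i], rsids[j], min(float(r2[i, j]), 1.0))
    return table


def simulate_two_sample(
    config: SimConfig, mode: str = "individual"
) -> tuple[SummaryStatsTable, SummaryStatsTable, LdTable, TrueParams]:
    """Simulate exposure and outcome summary statistics for one dataset pair.

    Returns (exposure table, outcome table, LD table, ground truth).
    Byte-identical for identical configs; changing ``outcome_seed`` alters
    only the outcome sample's noise.
    """
    if mode not in ("individual", "asymptotic"):
        raise SimulationConfigError(f"unknown simulation mode {mode!r}")
    if mode == "asymptotic" and config.ld_blocks:
        raise SimulationConfigError("asymptotic mode does not support LD blocks")
    streams = _streams(config)
    mafs, gamma, alpha, outlier_idx = _draw_effects(config, streams["params"])
    var_ex, var_ey = _noise_vars(config, mafs, gamma, alpha)
    rsids = tuple(f"{config.rsid_prefix}{j + 1:05d}" for j in range(config.m))
    pairs, swap, flip = _assign_alleles(config, streams["alleles"])

    if mode == "individual":
        rng_x = streams["exposure"]
        g_x = _genotypes(rng_x, config.n_exposure, mafs, config.ld_blocks)
        u_x = rng_x.standard_normal(config.n_exposure)
        x = (
            np.asarray(g_x, dtype=np.float64) @ gamma
            + config.confounder_x * u_x
            + np.sqrt(var_ex) * rng_x.standard_normal(config.n_exposure)
        )
        bx, sx, px, fx = _marginal_stats(g_x, x)

        rng_y = streams["outcome"]
        g_y = _genotypes(rng_y, config.n_outcome, mafs, config.ld_blocks)
        u_y = rng_y.standard_normal(config.n_outcome)
        x_out = (
            np.asarray(g_y, dtype=np.float64) @ gamma
            + config.confounder_x * u_y
            + np.sqrt(var_ex) * rng_y.standard_normal(config.n_outcome)
        )
        y = (
            config.theta * x_out
            + np.asarray(g_y, dtype=np.float64) @ alpha
            + config.confounder_y * u_y
            + np.sqrt(var_ey) * rng_y.standard_normal(config.n_outcome)
        )
        by, sy, py, fy = _marginal_stats(g_y, y)
        ld = _realized_ld(g_x, rsids)
    else:
        bx, sx, px, fx = _asymptotic_stats(streams["exposure"], gamma, mafs, config.n_exposure)
        mu_y = config.theta * gamma + alpha
        by, sy, py, fy = _asymptotic_stats(streams["outcome"], mu_y, mafs, config.n_outcome)
        ld = LdTable()

    exposure = _build_table(
        config.exposure_trait, config.exposure_source, rsids, pairs,
        bx, sx, px, fx, config.n_exposure,
    )
    outcome = _build_table(
        config.outcome_trait, config.outcome_source, rsids, pairs,
        by, sy, py, fy, config.n_outcome, swap=swap, flip=flip,
    )
    truth = TrueParams(
        theta=config.theta,
        gamma=gamma,
        alpha=alpha,
        mafs=mafs,
        rsids=rsids,
        causal_ids=tuple(rsids[j] for j in np.flatnonzero(gamma != 0)),
        outlier_ids=tuple(rsids[j] for j in outlier_idx),
    )
    return exposure, outcome, ld, truth


def gamma_for_f_targets(
    f_targets: np.ndarray, mafs: np.ndarray, n: int
) -> np.ndarray:
    """Per-SNP effects whose expected single-SNP F equals ``f_targets``."""
    return np.sqrt(np.asarray(f_targets, dtype=float) / (n * 2.0 * mafs * (1.0 - mafs)))


@dataclass(frozen=True)
class FixtureRegistry:
    """Bundled datasets emulating the study's instrument-count regimes."""

    tables: dict[str, SummaryStatsTable]
    ld: LdTable
    truths: dict[str, TrueParams]
    analyses: tuple[dict, ...]  # AnalysisSpec keyword sets, forward + reverse


# instrument counts of the bundled metabolite-like fixtures
METABOLITE_REGIMES = ((1, 5200), (2, 1960), (5, 7800), (22, 7824))
COMPLEX_TRAIT_N = 133413
COMPLEX_TRAIT_INSTRUMENTS = 73


def make_paper_regime_fixtures(seed: int) -> FixtureRegistry:
    """Deterministic registry: one complex trait (73 planted instruments,
    n ≈ 130k) and metabolite traits with 1, 2, 5 and 22 instruments.

    For every metabolite two dataset pairs are produced: a forward pair
    (metabolite exposure, null effect on the complex trait) and a reverse
    pair (complex-trait exposure, true effect −0.2 on the metabolite).
    """
    root = np.random.SeedSequence(seed)
    sub = root.generate_state(8)

    tables: dict[str, SummaryStatsTable] = {}
    truths: dict[str, TrueParams] = {}
    ld = LdTable()
    analyses: list[dict] = []

    # --- complex trait panel (shared across all reverse pairs) ---
    k_m = 120
    k_seed = int(sub[0])
    params_rng = np.random.default_rng(np.random.SeedSequence([k_seed, 0]))
    k_mafs = params_rng.uniform(0.05, 0.5, size=k_m)
    f_rng = np.random.default_rng(int(sub[1]))
    f_targets = np.zeros(k_m)
    f_targets[:COMPLEX_TRAIT_INSTRUMENTS] = f_rng.uniform(110, 600, COMPLEX_TRAIT_INSTRUMENTS)
    k_gamma = np.zeros(k_m)
    k_gamma[:COMPLEX_TRAIT_INSTRUMENTS] = gamma_for_f_targets(
        f_targets[:COMPLEX_TRAIT_INSTRUMENTS],
        k_mafs[:COMPLEX_TRAIT_INSTRUMENTS],
        COMPLEX_TRAIT_N,
    )

    for i, (n_inst, met_n) in enumerate(METABOLITE_REGIMES):
        met = f"met{n_inst:02d}"
        rev_config = SimConfig(
            m=k_m,
            n_exposure=COMPLEX_TRAIT_N,
            n_outcome=met_n,
            h2x=0.0,
            gamma=tuple(k_gamma),
            n_causal=COMPLEX_TRAIT_INSTRUMENTS,
            theta=-0.2,
            seed=k_seed,
            outcome_seed=int(sub[2]) + i,
            n_outliers=2 if n_inst == 22 else 0,
            outlier_shift=8.0,
            palindromic_frac=0.15,
            swap_frac=0.3,
            strand_flip_frac=0.2,
            rsid_prefix="rsk",
            exposure_trait="complex_trait",
            outcome_trait=met,
            exposure_source="sim_complex",
            outcome_source=f"sim_{met}",
        )
        exp_tab, out_tab, _, truth = simulate_two_sample(rev_config, mode="asymptotic")
        tables["complex_trait"] = exp_tab  # identical across i by construction
        tables[f"{met}_rev_outcome"] = out_tab
        truths[f"reverse_{met}"] = truth
        analyses.append(
            {
                "analysis_id": f"reverse_{met}",
                "direction": "reverse",
                "exposure_table": "complex_trait",
                "outcome_table": f"{met}_rev_outcome",
            }
        )

    # --- metabolite exposure panels (forward pairs, null causal effect) ---
    for i, (n_inst, met_n) in enumerate(METABOLITE_REGIMES):
        met = f"met{n_inst:02d}"
        m = n_inst + 30
        ld_blocks = ((2, 0.35),) if n_inst == 22 else None
        met_seed = int(sub[3]) + i
        met_params = np.random.default_rng(np.random.SeedSequence([met_seed, 0]))
        met_mafs = met_params.uniform(0.05, 0.5, size=m)
        met_f = np.zeros(m)
        met_f[:n_inst] = np.random.default_rng(int(sub[4]) + i).uniform(40, 130, n_inst)
        met_gamma = np.zeros(m)
        met_gamma[:n_inst] = gamma_for_f_targets(met_f[:n_inst], met_mafs[:n_inst], met_n)
        fw_config = SimConfig(
            m=m,
            n_exposure=met_n,
            n_outcome=COMPLEX_TRAIT_N,
            h2x=0.0,
            gamma=tuple(met_gamma),
            n_causal=n_inst,
            theta=0.0,
            seed=met_seed,
            outcome_seed=int(sub[5]) + i,
            ld_blocks=ld_blocks,
            palindromic_frac=0.15,
            swap_frac=0.3,
            strand_flip_frac=0.2,
            rsid_prefix=f"rsm{n_inst:02d}x",
            exposure_trait=met,
            outcome_trait="complex_trait",
            exposure_source=f"sim_{met}",
            outcome_source="sim_complex",
        )
        mode = "individual" if ld_blocks else "asymptotic"
        exp_tab, out_tab, pair_ld, truth = simulate_two_sample(fw_config, mode=mode)
        tables[met] = exp_tab
        tables[f"complex_fw_{met}"] = out_tab
        truths[f"forward_{met}"] = truth
        for (a, b), r2 in pair_ld.items():
            ld.add(a, b, r2)
        analyses.append(
            {
                "analysis_id": f"forward_{met}",
                "direction": "forward",
                "exposure_table": met,
                "outcome_table": f"complex_fw_{met}",
            }
        )

    analyses.sort(key=lambda a: a["analysis_id"])
    return FixtureRegistry(tables=tables, ld=ld, truths=truths, analyses=tuple(analyses))
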