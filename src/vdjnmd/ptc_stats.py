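"""Fold-reduction estimation and significance tests for PTC+ counts.

The central estimator is the odds-normalised fold reduction

    F = (n+_DNA / n-_DNA) / (n+_RNA / n-_RNA),

i.e. PTC+ abundance normalised to the PTC- molecules of the same pool as an
internal control.  Under the per-molecule decay model the RNA odds equal
the DNA odds times the molecular survival factor s, so F estimates 1/s
exactly; a fraction-mode estimator (ratio of PTC+ fractions) is retained
as an option.  Confidence intervals come from a nonparametric bootstrap of
both pools.

Two significance procedures accompany the estimate: an exact two-sided
binomial test of an RNA pool against the DNA PTC+ fraction
(minimum-likelihood convention), and a Monte Carlo comparison of the
fold reductions of two genotypes, whose null resamples every pool
binomially with both genotypes constrained to a common (pooled) survival
factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .decay_pools import MOLECULES, pool_counts


@dataclass(frozen=True)
class FoldReductionResult:
    """Fold reduction of PTC+ abundance in an RNA pool relative to DNA."""

    estimate: float
    mode: str
    ci_low: float
    ci_high: float
    n_ref: int
    n_obs: int
    lower_bound: bool = False
    n_boot: int = 0


@dataclass(frozen=True)
class TestResult:
    test_name: str
    p_value: float
    statistic: float
    n_iter: int | None = None
    seed: int | None = None
    observed_delta_logF: float | None = None
    n_degenerate: int = 0


def _validate_pool(counts: tuple[int, int], name: str) -> tuple[int, int]:
    pos, neg = int(counts[0]), int(counts[1])
    if pos < 0 or neg < 0:
        raise ValueError(f"{name} counts must be non-negative")
    if pos + neg == 0:
        raise ValueError(f"insufficient data: {name} pool is empty")
    return pos, neg


def _fold(rp, rn, op, on, mode: str):
    """Vectorised fold reduction with add-half (Haldane) correction of zeros."""
    rp, rn, op, on = (np.asarray(x, dtype=float) for x in (rp, rn, op, on))
    if mode == "odds":
        zero = (rp == 0) | (rn == 0) | (op == 0) | (on == 0)
        rp, rn, op, on = (np.where(zero, x + 0.5, x) for x in (rp, rn, op, on))
        return (rp / rn) / (op / on)
    # fraction mode
    zero = (rp == 0) | (op == 0)
    rp, op = np.where(zero, rp + 0.5, rp), np.where(zero, op + 0.5, op)
    return (rp / (rp + rn)) / (op / (op + on))


def fold_reduction(
    ref_counts: tuple[int, int],
    obs_counts: tuple[int, int],
    mode: str = "odds",
    n_boot: int = 10_000,
    rng: np.random.Generator | None = None,
    ci_level: float = 0.95,
) -> FoldReductionResult:
    """Fold reduction of the observed (RNA) pool relative to the reference (DNA) pool.

    A zero PTC+ count in the RNA pool yields a Haldane-corrected estimate
    flagged as a lower bound rather than an error.  The bootstrap resamples
    both pools with replacement (binomially at the observed fractions).
    """
    if mode not in ("odds", "fraction"):
        raise ValueError("mode must be 'odds' or 'fraction'")
    rp, rn = _validate_pool(ref_counts, "reference")
    op, on = _validate_pool(obs_counts, "observed")
    if mode == "odds" and (rn == 0 or on == 0):
        raise ValueError("insufficient data: odds mode needs PTC- counts in both pools")
    if mode == "fraction" and op + on == 0:
        raise ValueError("insufficient data: observed pool is empty")
    lower_bound = op == 0
    estimate = float(_fold(rp, rn, op, on, mode))

    rng = rng or np.random.default_rng()
    n_ref, n_obs = rp + rn, op + on
    bp = rng.binomial(n_ref, rp / n_ref, size=n_boot)
    bo = rng.binomial(n_obs, op / n_obs, size=n_boot)
    folds = _fold(bp, n_ref - bp, bo, n_obs - bo, mode)
    alpha = 1.0 - ci_level
    ci_low, ci_high = np.quantile(folds, [alpha / 2, 1.0 - alpha / 2])
    return FoldReductionResult(
        estimate=estimate,
        mode=mode,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_ref=n_ref,
        n_obs=n_obs,
        lower_bound=bool(lower_bound),
        n_boot=n_boot,
    )


def binomial_test(obs_counts: tuple[int, int], ref_fraction: float) -> TestResult:
    """Exact two-sided binomial test of an RNA pool against a reference PTC+ fraction."""
    op, on = _validate_pool(obs_counts, "observed")
    if not 0.0 < ref_fraction < 1.0:
        raise ValueError("ref_fraction must lie strictly inside (0, 1)")
    res = stats.binomtest(op, op + on, ref_fraction, alternative="two-sided")
    return TestResult(
        test_name="binomial_vs_reference",
        p_value=float(res.pvalue),
        statistic=float(op),
    )


def monte_carlo_compare(
    a_dna: tuple[int, int],
    a_rna: tuple[int, int],
    f_dna: tuple[int, int],
    f_rna: tuple[int, int],
    n_iter: int = 10_000,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> TestResult:
    """Monte Carlo test of equal fold reduction between two genotypes.

    Observed statistic: delta = log F_A - log F_F (odds mode).  Null
    resampling draws each DNA pool binomially at its own PTC+ fraction and
    each RNA pool at the fraction implied by that genotype's DNA odds times
    the survival odds pooled across both genotypes.  The p-value is
    (1 + #{|delta*| >= |delta|}) / (n_iter + 1), never reported as zero.
    Degenerate resamples (zero cells) are Haldane-corrected and counted.
    """
    if n_iter < 1000:
        raise ValueError("n_iter must be >= 1000")
    pools = {
        "a_dna": _validate_pool(a_dna, "A DNA"),
        "a_rna": _validate_pool(a_rna, "A RNA"),
        "f_dna": _validate_pool(f_dna, "F DNA"),
        "f_rna": _validate_pool(f_rna, "F RNA"),
    }
    if rng is None:
        rng = np.random.default_rng(seed)

    def odds(pos, neg):
        if pos == 0 or neg == 0:
            pos, neg = pos + 0.5, neg + 0.5
        return pos / neg

    fa = _fold(*pools["a_dna"], *pools["a_rna"], mode="odds")
    ff = _fold(*pools["f_dna"], *pools["f_rna"], mode="odds")
    delta = float(np.log(fa) - np.log(ff))

    s_pool = (
        odds(pools["a_rna"][0] + pools["f_rna"][0], pools["a_rna"][1] + pools["f_rna"][1])
        / odds(pools["a_dna"][0] + pools["f_dna"][0], pools["a_dna"][1] + pools["f_dna"][1])
    )
    draws = {}
    degenerate = np.zeros(n_iter, dtype=bool)
    for g in ("a", "f"):
        dp, dn = pools[f"{g}_dna"]
        rp, rn = pools[f"{g}_rna"]
        n_dna, n_rna = dp + dn, rp + rn
        f_dna_frac = dp / n_dna
        null_odds = odds(dp, dn) * s_pool
        f_rna_null = null_odds / (1.0 + null_odds)
        bd = rng.binomial(n_dna, f_dna_frac, size=n_iter)
        br = rng.binomial(n_rna, f_rna_null, size=n_iter)
        degenerate |= (bd == 0) | (bd == n_dna) | (br == 0) | (br == n_rna)
        draws[g] = (bd, n_dna - bd, br, n_rna - br)
    delta_star = np.log(_fold(*draws["a"], mode="odds")) - np.log(
        _fold(*draws["f"], mode="odds")
    )
    p = (1.0 + np.sum(np.abs(delta_star) >= abs(delta))) / (n_iter + 1.0)
    return TestResult(
        test_name="monte_carlo_fold_comparison",
        p_value=float(p),
        statistic=delta,
        n_iter=n_iter,
        seed=seed,
        observed_delta_logF=delta,
        n_degenerate=int(degenerate.sum()),
    )


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------

@dataclass
class Report:
    """Assembled per-pool statistics plus the cross-genotype comparison."""

    table: pd.DataFrame
    monte_carlo: TestResult | None
    mrna_vs_premrna: dict[str, TestResult]
    settings: dict = field(default_factory=dict)

    def text(self) -> str:
        lines = ["# vdjnmd report", "#"]
        for key, value in sorted(self.settings.items()):
            lines.append(f"# {key} = {value}")
        lines.append("#")
        lines.append(self.table.to_string(index=False))
        for genotype, tr in sorted(self.mrna_vs_premrna.items()):
            lines.append(
                f"binomial mRNA-vs-pre-mRNA [{genotype}]: p = {tr.p_value:.4g}"
            )
        if self.monte_carlo is not None:
            mc = self.monte_carlo
            lines.append(
                "monte carlo A-vs-F (mRNA fold reduction): "
                f"delta_logF = {mc.observed_delta_logF:.4f}, p = {mc.p_value:.4g} "
                f"(n_iter = {mc.n_iter}, degenerate resamples = {mc.n_degenerate})"
            )
        return "\n".join(lines) + "\n"


def summarize(
    counts: pd.DataFrame,
    mode: str = "odds",
    n_iter: int = 10_000,
    n_boot: int = 10_000,
    rng: np.random.Generator | None = None,
    settings: dict | None = None,
) -> Report:
    """Per-genotype fold reductions, binomial tests, and the A-vs-F Monte Carlo.

    ``counts`` is a published-shape count table (columns genotype, molecule,
    n_total, n_ptc_pos, n_ptc_neg) covering, per genotype, the dna,
    pre_mrna and mrna pools.  Binomial p-values compare each RNA pool to the
    DNA fraction; the mRNA-vs-pre-mRNA comparison is reported separately
    because the two published descriptions of the test disagree on the
    reference pool.
    """
    rng = rng or np.random.default_rng()
    genotypes = sorted(counts["genotype"].unique())
    missing = [
        (g, m)
        for g in genotypes
        for m in MOLECULES
        if counts[(counts["genotype"] == g) & (counts["molecule"] == m)].empty
    ]
    if missing:
        raise ValueError(f"missing pools: {missing}")

    rows = []
    mrna_vs_pre: dict[str, TestResult] = {}
    mrna_by_genotype: dict[str, tuple[int, int]] = {}
    dna_by_genotype: dict[str, tuple[int, int]] = {}
    for g in genotypes:
        dna = pool_counts(counts, g, "dna")
        dna_by_genotype[g] = dna
        f_dna = dna[0] / (dna[0] + dna[1])
        for molecule in ("pre_mrna", "mrna"):
            obs = pool_counts(counts, g, molecule)
            fr = fold_reduction(dna, obs, mode=mode, n_boot=n_boot, rng=rng)
            bt = binomial_test(obs, f_dna)
            rows.append(
                (
                    g,
                    molecule,
                    fr.estimate,
                    fr.ci_low,
                    fr.ci_high,
                    fr.lower_bound,
                    bt.p_value,
                )
            )
            if molecule == "mrna":
                mrna_by_genotype[g] = obs
        pre = pool_counts(counts, g, "pre_mrna")
        f_pre = pre[0] / (pre[0] + pre[1])
        if 0.0 < f_pre < 1.0:
            tr = binomial_test(mrna_by_genotype[g], f_pre)
            mrna_vs_pre[g] = TestResult(
                test_name="binomial_mrna_vs_premrna",
                p_value=tr.p_value,
                statistic=tr.statistic,
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "genotype",
            "molecule",
            "fold_reduction",
            "ci_low",
            "ci_high",
            "lower_bound",
            "p_binomial_vs_dna",
        ],
    )
    monte_carlo = None
    if {"A", "F"} <= set(genotypes):
        monte_carlo = monte_carlo_compare(
            dna_by_genotype["A"],
            mrna_by_genotype["A"],
            dna_by_genotype["F"],
            mrna_by_genotype["F"],
            n_iter=n_iter,
            rng=rng,
        )
    settings = dict(settings or {})
    settings.setdefault("mode", mode)
    settings.setdefault("n_iter", n_iter)
    settings.setdefault("n_boot", n_boot)
    return Report(
        table=table,
        monte_carlo=monte_carlo,
        mrna_vs_premrna=mrna_vs_pre,
        settings=settings,
    )
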