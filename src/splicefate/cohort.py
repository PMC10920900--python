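"""Cohort-level statistics for missplicing variant sets.

Implements the validation machinery applied to large variant cohorts:
permutation tests for depletion of population-observed variants among
predicted-deleterious subsets, the exact hypergeometric lower tail for the
same overlap, gene-level deleterious-rate permutation tests,
mutation-volume-controlled ranking of overrepresented genes (5 quantile
bins), driver-gene enrichment, and score benchmarking against clinical
labels (PPV by percentile, ROC/AUC).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from sklearn.metrics import roc_auc_score, roc_curve

from .errors import InputError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PermutationResult:
    """Outcome of a permutation test.

    ``p_value`` uses the add-one convention ((extreme + 1)/(iterations + 1)),
    so it is never exactly 0; ``p_display`` renders a floor result as
    "<1/iterations" in the style used for reported permutation tests.
    """

    observed: float
    null_mean: float
    n_extreme: int
    iterations: int
    seed: int
    tail: str  # lower | upper

    @property
    def p_value(self) -> float:
        return (self.n_extreme + 1) / (self.iterations + 1)

    @property
    def p_display(self) -> str:
        if self.n_extreme == 0:
            return f"<1/{self.iterations}"
        return f"{self.n_extreme / self.iterations:.6g}"


def permutation_depletion(
    pool_size: int,
    flagged_in_pool: int,
    subset_size: int,
    observed_flagged: int,
    iterations: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Permutation test for depletion of flagged items in a chosen subset.

    Each iteration draws ``subset_size`` items uniformly without
    replacement from a pool of ``pool_size`` of which ``flagged_in_pool``
    are flagged, and counts the flagged items drawn (a hypergeometric
    draw, sampled as such).  The p-value is the fraction of iterations
    with a count equal to or smaller than the observed one.
    """
    if subset_size > pool_size:
        raise InputError("subset_size exceeds pool_size")
    if flagged_in_pool > pool_size:
        raise InputError("flagged_in_pool exceeds pool_size")
    if observed_flagged > min(flagged_in_pool, subset_size):
        raise InputError("observed count infeasible")
    rng = np.random.default_rng(seed)
    counts = rng.hypergeometric(
        flagged_in_pool, pool_size - flagged_in_pool, subset_size, size=iterations
    )
    return PermutationResult(
        observed=float(observed_flagged),
        null_mean=float(counts.mean()),
        n_extreme=int((counts <= observed_flagged).sum()),
        iterations=iterations,
        seed=seed,
        tail="lower",
    )


@dataclass(frozen=True)
class HypergeomParams:
    """Counts for the depletion overlap test.

    ``N_unique`` unique mutations total, ``N_null`` of them flagged
    (e.g. observed in the healthy population), ``N_missplicing`` drawn
    (the missplicing subset), ``k_observed`` flagged among the drawn.
    """

    N_unique: int
    N_null: int
    N_missplicing: int
    k_observed: int

    def __post_init__(self) -> None:
        ok = 0 <= self.k_observed <= min(self.N_null, self.N_missplicing) <= self.N_unique
        if not ok or self.N_missplicing > self.N_unique or self.N_null > self.N_unique:
            raise InputError(f"infeasible hypergeometric counts: {self}")


def hypergeometric_lower_tail(p: HypergeomParams) -> float:
    """P(overlap <= k_observed) for the flagged-in-subset overlap.

    Exact sum of hypergeometric point masses from 0 to k_observed,
    evaluated in a numerically stable form for cohort-scale counts.
    """
    return float(hypergeom.cdf(p.k_observed, p.N_unique, p.N_null, p.N_missplicing))


def hypergeometric_upper_tail(p: HypergeomParams) -> float:
    """P(overlap >= k_observed) — the enrichment direction."""
    return float(hypergeom.sf(p.k_observed - 1, p.N_unique, p.N_null, p.N_missplicing))


def deleterious_rate_test(
    gene_ratios: dict[str, float],
    target_genes: set[str],
    iterations: int = 10_000,
    seed: int = 0,
) -> PermutationResult:
    """Are per-gene deleterious-mutation rates elevated in a target gene set?

    The observed statistic is the mean rate over the target genes; the
    null draws equally sized random gene sets from all genes.  Upper-tail
    p-value: fraction of random means >= the observed mean.
    """
    if not target_genes:
        raise InputError("empty target gene set")
    missing = target_genes - gene_ratios.keys()
    if missing:
        raise InputError(f"target genes absent from ratios: {sorted(missing)[:5]}")
    genes = sorted(gene_ratios)
    ratios = np.array([gene_ratios[g] for g in genes])
    target_mask = np.array([g in target_genes for g in genes])
    observed = float(ratios[target_mask].mean())
    rng = np.random.default_rng(seed)
    k = int(target_mask.sum())
    null = np.empty(iterations)
    for i in range(iterations):
        null[i] = ratios[rng.choice(len(ratios), size=k, replace=False)].mean()
    return PermutationResult(
        observed=observed,
        null_mean=float(null.mean()),
        n_extreme=int((null >= observed - 1e-12).sum()),
        iterations=iterations,
        seed=seed,
        tail="upper",
    )


def gene_counts(df: pd.DataFrame, n_bins: int = 5) -> pd.DataFrame:
    """Derive mutation ratios and volume bins from per-gene counts.

    ``df`` needs columns gene, N_unique, N_mis, N_del.  Adds R_mis, R_del
    and a quantile ``bin`` (0-based) over N_unique, rank-based with ties
    broken by gene id so the partition is deterministic.
    """
    required = {"gene", "N_unique", "N_mis", "N_del"}
    if not required <= set(df.columns):
        raise InputError(f"gene counts need columns {sorted(required)}")
    if (df["N_unique"] < 1).any():
        raise InputError("every gene needs N_unique >= 1")
    if ((df["N_del"] > df["N_mis"]) | (df["N_mis"] > df["N_unique"])).any():
        raise InputError("need N_del <= N_mis <= N_unique per gene")
    out = df.copy()
    out["R_mis"] = out["N_mis"] / out["N_unique"]
    out["R_del"] = out["N_del"] / out["N_unique"]
    n_bins_eff = min(n_bins, len(out))
    if n_bins_eff < n_bins:
        logger.warning("only %d genes: using %d volume bins", len(out), n_bins_eff)
    order = out.sort_values(["N_unique", "gene"]).index
    ranks = pd.Series(np.arange(len(out)), index=order)
    out["bin"] = (ranks * n_bins_eff // len(out)).reindex(out.index)
    return out


def rank_overrepresented_genes(
    counts: pd.DataFrame,
    ratio: str = "R_del",
    top_percent: float = 0.05,
) -> set[str]:
    """Top genes by missplicing/deleterious ratio within each volume bin.

    Within each mutation-volume quantile bin, genes are sorted by the
    chosen ratio (descending, ties by gene id) and the top
    ``ceil(top_percent · bin size)`` are taken; the union over bins is
    returned.  Binning controls for the volume bias that makes heavily
    mutated genes look overrepresented.
    """
    if ratio not in {"R_mis", "R_del"}:
        raise InputError("ratio must be R_mis or R_del")
    if "bin" not in counts.columns:
        counts = gene_counts(counts)
    selected: set[str] = set()
    for _, grp in counts.groupby("bin"):
        quota = math.ceil(top_percent * len(grp))
        ordered = grp.sort_values([ratio, "gene"], ascending=[False, True])
        selected.update(ordered["gene"].head(quota))
    return selected


def driver_enrichment(
    selected: set[str],
    drivers: set[str],
    universe: set[str],
    iterations: int = 1000,
    seed: int = 0,
) -> tuple[int, PermutationResult, float]:
    """Enrichment of known drivers in a selected gene set.

    Each iteration draws ``|selected|`` genes uniformly without
    replacement from the universe and counts drivers among them.  Returns
    (observed overlap, upper-tail permutation result, upper-tail exact
    hypergeometric p).
    """
    if not universe:
        raise InputError("empty universe")
    if not selected <= universe or not drivers <= universe:
        raise InputError("selected and drivers must be subsets of the universe")
    genes = sorted(universe)
    driver_mask = np.array([g in drivers for g in genes])
    overlap = len(selected & drivers)
    rng = np.random.default_rng(seed)
    k = len(selected)
    null = np.empty(iterations)
    for i in range(iterations):
        null[i] = driver_mask[rng.choice(len(genes), size=k, replace=False)].sum()
    perm = PermutationResult(
        observed=float(overlap),
        null_mean=float(null.mean()),
        n_extreme=int((null >= overlap).sum()),
        iterations=iterations,
        seed=seed,
        tail="upper",
    )
    hyper_p = hypergeometric_upper_tail(
        HypergeomParams(len(universe), len(drivers), len(selected), overlap)
    )
    return overlap, perm, hyper_p


@dataclass(frozen=True)
class BenchmarkCurves:
    """Score-vs-label benchmarking output."""

    ppv_by_percentile: tuple[tuple[float, float], ...]
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    auc: float


def benchmark_scores(
    scores: dict[str, float],
    labels: dict[str, str],
    percentiles: np.ndarray | None = None,
) -> BenchmarkCurves:
    """PPV at incremental score percentiles plus ROC over the labeled items.

    Labels are pathogenic / benign / ambiguous.  Percentile cuts are taken
    over all scored items; PPV at a cut is pathogenic/(pathogenic+benign)
    among items at or above the cut (ambiguous excluded from the
    denominator).  ROC and AUC use pathogenic vs benign only.
    """
    if percentiles is None:
        percentiles = np.arange(5, 100, 5)
    items = sorted(scores)
    values = np.array([scores[i] for i in items])
    lab = np.array([labels.get(i, "ambiguous") for i in items])
    n_path, n_ben = int((lab == "pathogenic").sum()), int((lab == "benign").sum())
    if n_path + n_ben == 0:
        raise InputError("all items are ambiguous: PPV undefined")

    ppv: list[tuple[float, float]] = []
    for pct in percentiles:
        cut = np.percentile(values, pct)
        at_cut = values >= cut
        tp = int(((lab == "pathogenic") & at_cut).sum())
        fp = int(((lab == "benign") & at_cut).sum())
        ppv.append((float(pct), tp / (tp + fp) if tp + fp else float("nan")))

    if n_path == 0 or n_ben == 0:
        raise InputError("ROC needs at least one pathogenic and one benign item")
    keep = lab != "ambiguous"
    y = (lab[keep] == "pathogenic").astype(int)
    fpr, tpr, _ = roc_curve(y, values[keep])
    return BenchmarkCurves(
        ppv_by_percentile=tuple(ppv),
        roc_fpr=fpr,
        roc_tpr=tpr,
        auc=float(roc_auc_score(y, values[keep])),
    )


def build_survival_groups(
    mutations: pd.DataFrame,
    gene_set: set[str],
) -> pd.DataFrame:
    """Affected/unaffected patient groups for downstream survival analysis.

    ``mutations`` needs columns patient_id, gene, is_missplicing,
    is_deleterious (booleans).  Affected = at least one deleterious
    mutation in ``gene_set``; unaffected = no missplicing mutation in
    ``gene_set``; patients matching neither rule are excluded.  The
    survival fit itself is standard and left to survival libraries.
    """
    required = {"patient_id", "gene", "is_missplicing", "is_deleterious"}
    if not required <= set(mutations.columns):
        raise InputError(f"mutations table needs columns {sorted(required)}")
    in_set = mutations["gene"].isin(gene_set)
    per_patient = mutations.assign(
        del_in_set=mutations["is_deleterious"] & in_set,
        mis_in_set=mutations["is_missplicing"] & in_set,
    ).groupby("patient_id")[["del_in_set", "mis_in_set"]].any()
    rows = []
    for patient, row in per_patient.iterrows():
        if row["del_in_set"]:
            rows.append((patient, "affected"))
        elif not row["mis_in_set"]:
            rows.append((patient, "unaffected"))
    return pd.DataFrame(rows, columns=["patient_id", "group"])


def match_mutation_volume(
    groups: pd.DataFrame,
    volumes: dict[str, int],
    lower_pct: float,
    upper_pct: float,
) -> pd.DataFrame:
    """Restrict survival groups to a mutation-volume percentile band.

    Controls for the volume bias between affected and unaffected patients
    by keeping only patients whose total mutation count falls between the
    two percentiles of the pooled volume distribution.
    """
    vols = np.array([volumes[p] for p in groups["patient_id"]])
    lo, hi = np.percentile(vols, [lower_pct, upper_pct])
    return groups[(vols >= lo) & (vols <= hi)].reset_index(drop=True)
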