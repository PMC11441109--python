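"""Count normalization, two-group negative-binomial differential
expression, and Fisher-exact term enrichment.

The differential-expression test is a plain NB Wald test: median-of-ratios
size factors, group means with a 0.5 pseudocount, a pooled
method-of-moments dispersion per feature (floored at 1e-8), and a Wald
statistic on log2FC referred to a t distribution with ``n_a + n_b - 2``
degrees of freedom — the standard plug-in correction that keeps the
small-sample type-I error near nominal at three replicates per group.
Shrinkage estimators of full DESeq2-style machinery are intentionally not
reproduced: downstream stages consume only sign/threshold calls.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Optional, Sequence, Set

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DISPERSION_FLOOR = 1e-8
#: weight of the across-feature median in the moderated dispersion estimate
PRIOR_DF = 10


def size_factors(matrix: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors, one per sample (column).

    factor_j = median over features with all-positive counts of
    count_ij / geometric-mean_i.  Raises when no feature is positive in
    every sample (a pseudo-reference fallback such as averaging log counts
    over positive entries is then required; see ``library_size_factors``).
    """
    counts = matrix.to_numpy(dtype=float)
    all_positive = (counts > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "no feature has positive counts in every sample; median-of-ratios "
            "is undefined — use a pseudo-reference (e.g. library_size_factors)"
        )
    sub = counts[all_positive]
    log_geo_mean = np.log(sub).mean(axis=1)
    factors = np.exp(np.median(np.log(sub) - log_geo_mean[:, None], axis=0))
    return pd.Series(factors, index=matrix.columns, name="size_factor")


def library_size_factors(matrix: pd.DataFrame) -> pd.Series:
    """Total-count factors scaled to geometric mean 1 (miRNA tables, where
    most features are structurally zero in some condition)."""
    totals = matrix.sum(axis=0).astype(float)
    if (totals <= 0).any():
        raise ValueError("every sample needs a positive library size")
    factors = totals / np.exp(np.log(totals).mean())
    return pd.Series(factors, index=matrix.columns, name="size_factor")


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(
    matrix: pd.DataFrame,
    condition_a: Sequence[str],
    condition_b: Sequence[str],
    fc_threshold: float = 1.5,
    alpha: float = 0.05,
    factors: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Two-group NB Wald differential expression, b versus a.

    ``condition_a``/``condition_b`` are sample-id lists (reference and test
    group).  Features with zero counts in all selected samples are dropped.
    Returns a DataFrame indexed by feature with columns baseMeanA,
    baseMeanB, log2FC, pvalue, fdr and call in {up, down, ns}; calls need
    ``|log2FC| >= fc_threshold`` and ``fdr < alpha``.
    """
    a, b = list(condition_a), list(condition_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each condition needs >= 2 replicates for a dispersion estimate")
    missing = [s for s in a + b if s not in matrix.columns]
    if missing:
        raise KeyError(f"samples absent from the count matrix: {missing}")
    sub = matrix[a + b]
    sub = sub.loc[sub.sum(axis=1) > 0]
    if factors is None:
        factors = size_factors(sub)
    q = sub.div(factors[a + b], axis=1)
    qa, qb = q[a].to_numpy(), q[b].to_numpy()
    na, nb = len(a), len(b)

    mean_a, mean_b = qa.mean(axis=1), qb.mean(axis=1)
    log2fc = np.log2((mean_b + 0.5) / (mean_a + 0.5))

    var_a = qa.var(axis=1, ddof=1)
    var_b = qb.var(axis=1, ddof=1)
    pooled_var = ((na - 1) * var_a + (nb - 1) * var_b) / (na + nb - 2)
    pooled_mean = (na * mean_a + nb * mean_b) / (na + nb)
    res_df = na + nb - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        raw_dispersion = (pooled_var - pooled_mean) / pooled_mean**2
    raw_dispersion = np.where(np.isfinite(raw_dispersion), raw_dispersion, 0.0)
    # moderate the few-replicate moment estimates toward the across-feature
    # median (information sharing as in DESeq2/edgeR, in its simplest form);
    # the widened t reference below accounts for the borrowed df
    prior = float(np.median(raw_dispersion)) if len(raw_dispersion) else 0.0
    dispersion = (res_df * raw_dispersion + PRIOR_DF * prior) / (res_df + PRIOR_DF)
    dispersion = np.maximum(dispersion, DISPERSION_FLOOR)

    # delta-method variance of log2(group mean + pseudocount) under NB
    var_mean_a = (mean_a + dispersion * mean_a**2) / na
    var_mean_b = (mean_b + dispersion * mean_b**2) / nb
    se = np.sqrt(
        var_mean_a / (mean_a + 0.5) ** 2 + var_mean_b / (mean_b + 0.5) ** 2
    ) / np.log(2)
    se = np.maximum(se, 1e-12)
    wald = log2fc / se
    pvalue = 2.0 * stats.t.sf(np.abs(wald), df=res_df + PRIOR_DF)
    fdr = bh_adjust(pvalue)

    call = np.where(
        (np.abs(log2fc) >= fc_threshold) & (fdr < alpha),
        np.where(log2fc > 0, "up", "down"),
        "ns",
    )
    return pd.DataFrame(
        {
            "baseMeanA": mean_a,
            "baseMeanB": mean_b,
            "log2FC": log2fc,
            "pvalue": pvalue,
            "fdr": fdr,
            "call": call,
        },
        index=sub.index,
    )


def term_enrichment(
    selected: Iterable[str],
    universe: Iterable[str],
    term_map: Mapping[str, Set[str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per term with BH control.

    ``term_map`` maps term -> feature set.  Terms with no carrier in the
    universe are skipped with a warning.  Returns a DataFrame indexed by
    term with columns n_selected, n_universe, pvalue, fdr, enriched.
    """
    selected = set(selected)
    universe = set(universe)
    if not selected <= universe:
        raise ValueError("selected features must be a subset of the universe")
    rows = {}
    for term, carriers in term_map.items():
        in_universe = set(carriers) & universe
        if not in_universe:
            warnings.warn(f"term {term!r} has no carrier in the universe; skipped")
            continue
        k = len(selected & in_universe)
        rows[term] = {
            "n_selected": k,
            "n_universe": len(in_universe),
            "pvalue": stats.hypergeom.sf(
                k - 1, len(universe), len(in_universe), len(selected)
            ),
        }
    result = pd.DataFrame.from_dict(rows, orient="index")
    if result.empty:
        return pd.DataFrame(
            columns=["n_selected", "n_universe", "pvalue", "fdr", "enriched"]
        )
    result["fdr"] = bh_adjust(result["pvalue"])
    result["enriched"] = result["fdr"] < alpha
    return result.sort_values("pvalue")
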