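"""Consensus miRNA-target inference with anticorrelation background testing.

A (miRNA, transcript) pair survives four filters applied in fixed order:

1. **consensus** — predicted by at least ``min_plant_tools`` plant-style
   tools or ``min_animal_tools`` animal-style tools;
2. **opposite expression** — the miRNA is differentially expressed
   (|log2FC| >= threshold and FDR < alpha) and the transcript is
   significantly changed (FDR only, no fold-change threshold) with the
   opposite sign;
3. **anticorrelation** — Spearman correlation of normalized miRNA and
   transcript counts across matched samples at most ``spearman_max``;
4. **background** — the pair's correlation is lower than the same miRNA's
   correlation with the other transcripts of the target's organism
   (one-sided rank test at ``wilcoxon_alpha``; with a single target-side
   value this degenerates to the empirical percentile
   ``p = (1 + #{background <= r}) / (1 + |background|)``).

The verdict records the first failing stage.  Pairs whose miRNA and
transcript come from different species are cross-kingdom, otherwise
endogenous.

Two built-in plant-style predictors make the consensus stage exercisable
without external tool tables: a position-weighted complementarity scorer
(gapless, G:U wobble 0.5, mismatch 1.0, penalties doubled in the seed,
miRNA positions 2-13, site kept when the total is at most ``cutoff``) and a
strict seed matcher requiring perfect Watson-Crick pairing of positions
2-13.  External prediction tables (mirna_id, transcript_id, tool, style,
score) are consumed as additional tools.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .config import condition_species
from .seq import normalize_rna, reverse_complement

SEED_START, SEED_END = 2, 13  # 1-based miRNA positions with doubled penalties

_BASE_INDEX = {b: i for i, b in enumerate("ACGU")}
# pair penalty[miRNA base, transcript base]: Watson-Crick 0, G:U wobble 0.5
_PAIR_PENALTY = np.ones((4, 4))
for _m, _t in (("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")):
    _PAIR_PENALTY[_BASE_INDEX[_m], _BASE_INDEX[_t]] = 0.0
for _m, _t in (("G", "U"), ("U", "G")):
    _PAIR_PENALTY[_BASE_INDEX[_m], _BASE_INDEX[_t]] = 0.5


@dataclass(frozen=True)
class FilterThresholds:
    """Tunable cutoffs of the inference cascade."""

    min_plant_tools: int = 2
    min_animal_tools: int = 3
    target_fdr_alpha: float = 0.05
    mirna_fc_threshold: float = 1.5
    spearman_max: float = -0.4
    wilcoxon_alpha: float = 0.1
    expectation_cutoff: float = 5.0

    def __post_init__(self):
        if self.spearman_max >= 0:
            raise ValueError("spearman_max must be negative")
        for name in ("target_fdr_alpha", "wilcoxon_alpha"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in (0, 1)")

    @classmethod
    def profile(cls, name: str) -> "FilterThresholds":
        """Named presets: "lenient" (spearman_max -0.4) or "strict" (-0.7)."""
        if name == "lenient":
            return cls()
        if name == "strict":
            return cls(spearman_max=-0.7)
        raise ValueError(f"unknown profile {name!r}")


# ---------------------------------------------------------------------------
# built-in predictors
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8).copy()


_ENCODE_LUT = np.zeros(128, dtype=np.int8)
for _b, _i in _BASE_INDEX.items():
    _ENCODE_LUT[ord(_b)] = _i


def surrogate_expectation(
    mirna: str, transcript: str, cutoff: float = 5.0
) -> Optional[Tuple[float, int]]:
    """Best gapless complementarity site of a miRNA on a transcript.

    Slides the reverse-complemented mature sequence along the transcript;
    per miRNA position (1 = 5' end) Watson-Crick pairs score 0, G:U wobble
    0.5, mismatches 1.0, doubled within the seed (positions 2-13); the site
    score is the sum.  Returns ``(score, start)`` of the minimal-score site
    (leftmost tie-break, 0-based start) when the score is at most
    ``cutoff``, else None.
    """
    m = normalize_rna(mirna)
    t = normalize_rna(transcript)
    L, n = len(m), len(t)
    if n < L:
        return None
    m_idx = _ENCODE_LUT[_encode(m)]
    t_idx = _ENCODE_LUT[_encode(t)]
    # window position j pairs miRNA position i = L - j (1-based)
    penalties = _PAIR_PENALTY[m_idx[::-1]]  # (L, 4): row j = miRNA base at pos L-j
    weights = np.where(
        (np.arange(L, 0, -1) >= SEED_START) & (np.arange(L, 0, -1) <= SEED_END), 2.0, 1.0
    )
    windows = np.lib.stride_tricks.sliding_window_view(t_idx, L)  # (n-L+1, L)
    scores = (penalties[np.arange(L)[None, :], windows] * weights[None, :]).sum(axis=1)
    best = int(np.argmin(scores))
    if scores[best] > cutoff:
        return None
    return float(scores[best]), best


def seed_match(mirna: str, transcript: str) -> bool:
    """Perfect Watson-Crick complementarity of seed positions 2-13 anywhere
    on the transcript."""
    m = normalize_rna(mirna)
    probe = reverse_complement(m[SEED_START - 1 : SEED_END])
    return probe in normalize_rna(transcript)


def predict_targets(
    catalog: Mapping[str, str],
    transcripts: Mapping[str, str],
    cutoff: float = 5.0,
) -> pd.DataFrame:
    """Run both built-in plant-style predictors over all pairs.

    Returns the standard prediction-table layout:
    (mirna_id, transcript_id, tool, style, score).
    """
    rows = []
    for mid in sorted(catalog):
        mature = catalog[mid]
        for tid in sorted(transcripts):
            hit = surrogate_expectation(mature, transcripts[tid], cutoff)
            if hit is not None:
                rows.append((mid, tid, "expectation", "plant", hit[0]))
            if seed_match(mature, transcripts[tid]):
                rows.append((mid, tid, "seedmatch", "plant", 0.0))
    return pd.DataFrame(
        rows, columns=["mirna_id", "transcript_id", "tool", "style", "score"]
    )


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def consensus_filter(
    predictions: pd.DataFrame, thresholds: FilterThresholds = FilterThresholds()
) -> pd.DataFrame:
    """Collapse prediction tables to per-pair tool votes.

    A pair passes when it has >= min_plant_tools plant-style votes OR
    >= min_animal_tools animal-style votes.  Duplicate (tool, pair) rows
    collapse to a single vote.
    """
    required = {"mirna_id", "transcript_id", "tool", "style"}
    if not required <= set(predictions.columns):
        raise ValueError(f"prediction table needs columns {sorted(required)}")
    bad_styles = set(predictions["style"]) - {"plant", "animal"}
    if bad_styles:
        raise ValueError(f"unknown prediction styles: {sorted(bad_styles)}")
    dedup = predictions.drop_duplicates(["mirna_id", "transcript_id", "tool", "style"])
    rows = []
    for (mid, tid), grp in dedup.groupby(["mirna_id", "transcript_id"], sort=True):
        plant_votes = sorted(grp.loc[grp["style"] == "plant", "tool"].unique())
        animal_votes = sorted(grp.loc[grp["style"] == "animal", "tool"].unique())
        score = np.nan
        exp_rows = grp.loc[grp["tool"] == "expectation", "score"]
        if len(exp_rows):
            score = float(exp_rows.iloc[0])
        rows.append(
            {
                "mirna_id": mid,
                "transcript_id": tid,
                "tool_votes": ";".join(plant_votes + animal_votes),
                "n_plant_tools": len(plant_votes),
                "n_animal_tools": len(animal_votes),
                "expectation": score,
                "consensus": len(plant_votes) >= thresholds.min_plant_tools
                or len(animal_votes) >= thresholds.min_animal_tools,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "mirna_id",
            "transcript_id",
            "tool_votes",
            "n_plant_tools",
            "n_animal_tools",
            "expectation",
            "consensus",
        ],
    )


def opposite_expression(
    mirna_row: Optional[pd.Series],
    transcript_row: Optional[pd.Series],
    thresholds: FilterThresholds,
) -> Tuple[bool, str]:
    """(passes, reason).  miRNA needs a significant thresholded call; the
    transcript needs FDR significance only (no fold-change threshold)."""
    if mirna_row is None or transcript_row is None:
        return False, "untested"
    mirna_ok = (
        abs(mirna_row["log2FC"]) >= thresholds.mirna_fc_threshold
        and mirna_row["fdr"] < thresholds.target_fdr_alpha
    )
    transcript_ok = (
        transcript_row["fdr"] < thresholds.target_fdr_alpha
        and transcript_row["log2FC"] != 0
    )
    if not (mirna_ok and transcript_ok):
        return False, "not_de"
    if np.sign(mirna_row["log2FC"]) == np.sign(transcript_row["log2FC"]):
        return False, "same_sign"
    return True, ""


def pair_correlation(
    mirna_counts: pd.Series, transcript_counts: pd.Series
) -> Tuple[float, float]:
    """Spearman (mean ranks on ties) and Pearson across matched samples.

    Inputs must be size-factor-normalized counts indexed by the same
    samples.  Returns (nan, nan) when either vector is constant.
    """
    if list(mirna_counts.index) != list(transcript_counts.index):
        diff = set(mirna_counts.index) ^ set(transcript_counts.index)
        raise ValueError(f"mismatched sample sets: {sorted(diff)}")
    if len(mirna_counts) < 4:
        raise ValueError("need >= 4 matched samples for a correlation")
    x = mirna_counts.to_numpy(dtype=float)
    y = transcript_counts.to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    rho = stats.spearmanr(x, y).statistic
    r = stats.pearsonr(x, y).statistic
    return float(rho), float(r)


def background_test(
    target_correlation: float,
    background_correlations: Sequence[float],
    wilcoxon_alpha: float = 0.1,
) -> float:
    """One-sided test that the target-side correlation is stochastically
    smaller than the miRNA's background correlations.

    With a single target value this is the empirical percentile
    ``p = (1 + #{background <= r}) / (1 + n_background)``; a set of
    target-side values uses the one-sided rank-sum test.  The pass rule is
    strict: ``p < wilcoxon_alpha``.
    """
    background = np.asarray(
        [b for b in background_correlations if np.isfinite(b)], dtype=float
    )
    if background.size == 0:
        raise ValueError("background correlation set is empty")
    if background.size < 10:
        warnings.warn(
            f"background of size {background.size} < 10: percentile test is low-powered"
        )
    target = np.atleast_1d(np.asarray(target_correlation, dtype=float))
    if target.size == 1:
        return float((1 + np.sum(background <= target[0])) / (1 + background.size))
    return float(
        stats.mannwhitneyu(target, background, alternative="less").pvalue
    )


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def correlation_samples(
    sample_conditions: Mapping[str, str], species_a: str, species_b: str
) -> List[str]:
    """Samples of conditions in which both species are physically present
    (endogenous pair: own control plus interactions; cross-kingdom pair:
    interaction conditions only)."""
    return [
        s
        for s, cond in sample_conditions.items()
        if {species_a, species_b} <= set(condition_species(cond))
    ]


def classify_and_report(
    predictions: pd.DataFrame,
    mirna_de: pd.DataFrame,
    transcript_de: pd.DataFrame,
    mirna_norm: pd.DataFrame,
    transcript_norm: Mapping[str, pd.DataFrame],
    mirna_species: Mapping[str, str],
    transcript_species: Mapping[str, str],
    sample_conditions: Mapping[str, str],
    thresholds: FilterThresholds = FilterThresholds(),
) -> pd.DataFrame:
    """Full cascade over every predicted pair, one row per pair.

    ``mirna_norm`` and the per-species ``transcript_norm`` matrices hold
    size-factor-normalized counts over (at least) all interaction and
    control samples; correlations use the samples of every condition in
    which both features' species are present.  The verdict column records
    the first failing stage; retained pairs sort first, by Spearman
    ascending.
    """
    votes = consensus_filter(predictions, thresholds)
    bg_cache: Dict[Tuple[str, str], pd.Series] = {}

    def _background(mid: str, species: str) -> pd.Series:
        key = (mid, species)
        if key not in bg_cache:
            samples = correlation_samples(
                sample_conditions, mirna_species[mid], species
            )
            mat = transcript_norm[species][samples]
            x = mirna_norm.loc[mid, samples].to_numpy(dtype=float)
            xr = stats.rankdata(x)
            ranks = np.apply_along_axis(stats.rankdata, 1, mat.to_numpy(dtype=float))
            xc = xr - xr.mean()
            rc = ranks - ranks.mean(axis=1, keepdims=True)
            denom = np.sqrt((xc**2).sum() * (rc**2).sum(axis=1))
            with np.errstate(invalid="ignore", divide="ignore"):
                rho = (rc @ xc) / denom
            if np.ptp(x) == 0:
                rho[:] = np.nan
            bg_cache[key] = pd.Series(rho, index=mat.index)
        return bg_cache[key]

    rows = []
    for rec in votes.itertuples(index=False):
        mid, tid = rec.mirna_id, rec.transcript_id
        t_species = transcript_species[tid]
        relationship = (
            "cross_kingdom" if mirna_species[mid] != t_species else "endogenous"
        )
        row = {
            "mirna_id": mid,
            "transcript_id": tid,
            "species_of_transcript": t_species,
            "relationship": relationship,
            "tool_votes": rec.tool_votes,
            "expectation": rec.expectation,
            "opposite_expression": False,
            "spearman": np.nan,
            "pearson": np.nan,
            "background_p": np.nan,
            "verdict": "retained",
            "reason": "",
        }
        rows.append(row)
        if not rec.consensus:
            row["verdict"] = "rejected_consensus"
            continue
        m_row = mirna_de.loc[mid] if mid in mirna_de.index else None
        t_row = transcript_de.loc[tid] if tid in transcript_de.index else None
        ok, reason = opposite_expression(m_row, t_row, thresholds)
        row["opposite_expression"] = ok
        if not ok:
            row["verdict"], row["reason"] = "rejected_expression", reason
            continue
        samples = correlation_samples(sample_conditions, mirna_species[mid], t_species)
        if len(samples) < 4:
            row["verdict"], row["reason"] = "rejected_correlation", "insufficient_samples"
            continue
        rho, r = pair_correlation(
            mirna_norm.loc[mid, samples], transcript_norm[t_species].loc[tid, samples]
        )
        row["spearman"], row["pearson"] = rho, r
        if not np.isfinite(rho):
            row["verdict"], row["reason"] = "rejected_correlation", "degenerate"
            continue
        if rho > thresholds.spearman_max:
            row["verdict"], row["reason"] = "rejected_correlation", "above_threshold"
            continue
        background = _background(mid, t_species).drop(index=tid, errors="ignore")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = background_test(rho, background.tolist(), thresholds.wilcoxon_alpha)
        row["background_p"] = p
        if not p < thresholds.wilcoxon_alpha:
            row["verdict"], row["reason"] = "rejected_background", ""

    table = pd.DataFrame(rows)
    if table.empty:
        return table
    retained = table[table["verdict"] == "retained"].sort_values(
        ["spearman", "mirna_id", "transcript_id"]
    )
    rejected = table[table["verdict"] != "retained"].sort_values(
        ["mirna_id", "transcript_id"]
    )
    return pd.concat([retained, rejected], ignore_index=True)
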