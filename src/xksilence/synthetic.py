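"""Synthetic two-species experiment with planted ground truth.

The generator emulates the statistical structure a dual-species
sRNA/mRNA integration analysis assumes, at desk scale:

* two transcriptome references (plant, fungus), a configurable fraction of
  fungal transcripts duplicated into the plant set to create ambiguous
  (homologous) reads;
* planted mature miRNAs whose reverse complement is embedded in their target
  transcripts, in endogenous (within-species) and cross-kingdom pairs;
* negative-binomial count matrices with planted differential expression and
  a miRNA-coupled repression term that anticorrelates target transcript
  abundance with the targeting miRNA across samples;
* per-sample small-RNA read pools composed of mature-miRNA copies (at most
  one substitution per read), sense/antisense transcript degradation
  fragments, structural-RNA contaminants and out-of-length-range fragments.

A single RNG stream keyed by the seed is consumed in fixed stage order
(references -> miRNAs/targets -> count matrices -> reads), so identical
configurations produce byte-identical outputs.

Planted target model
--------------------
For a pair (miRNA m, transcript t) with repression strength ``rep`` the mean
of t in sample j is::

    mu_tj = base_t * 2^(rep * [j is interaction]) * 2^(-rep * a_mj / base_m)

where ``a_mj`` is m's realized abundance and ``base_m`` its control-level
expectation (the second factor applies only where m's species is present).
The baseline is thereby the fully repressed state: lowering the miRNA
derepresses the target, giving the opposite-sign differential expression and
the across-sample anticorrelation the downstream inference looks for, while
``rep = 0`` makes planted targets distributionally identical to background.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .config import ConfigurationError, SimulationConfig, condition_species, is_interaction
from .reads import SmallRNARead
from .seq import reverse_complement

RNA_BASES = np.array(list("ACGU"))


def _random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(RNA_BASES, size=length))


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws with Var = mu + dispersion * mu^2.

    Falls back to Poisson in the small-dispersion limit.
    """
    mu = np.asarray(mu, dtype=float)
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    if not np.any(pos):
        return out
    if dispersion < 1e-12:
        out[pos] = rng.poisson(mu[pos])
    else:
        r = 1.0 / dispersion
        p = r / (r + mu[pos])
        out[pos] = rng.negative_binomial(r, p)
    return out


@dataclass
class GroundTruthManifest:
    """Everything the generator planted, for oracle-style testing."""

    #: id -> {"seq", "species", "responsive", "base"} (base = control-level copies)
    mirnas: Dict[str, dict] = field(default_factory=dict)
    #: expected mature copies per miRNA x sample (floats; the coupling latent)
    abundance: Optional[pd.DataFrame] = None
    #: planted pairs: mirna_id, transcript_id, relationship, species_of_transcript,
    #: site_start, site_end (0-based half-open), repression_log2fc
    pairs: List[dict] = field(default_factory=list)
    #: (plant_id, fungus_id) transcript pairs with identical sequence
    homologous: List[Tuple[str, str]] = field(default_factory=list)
    structural: List[str] = field(default_factory=list)
    #: transcript id -> signed true log2FC (interaction vs control)
    de_transcripts: Dict[str, float] = field(default_factory=dict)
    #: transcript id -> species
    transcripts: Dict[str, str] = field(default_factory=dict)
    #: ordered (sample_id, condition)
    samples: List[Tuple[str, str]] = field(default_factory=list)

    def mirna_species(self, mirna_id: str) -> str:
        return self.mirnas[mirna_id]["species"]

    def planted_pair_keys(self, relationship: Optional[str] = None):
        return {
            (p["mirna_id"], p["transcript_id"])
            for p in self.pairs
            if relationship is None or p["relationship"] == relationship
        }

    def to_json(self, path) -> None:
        payload = {
            "mirnas": self.mirnas,
            "abundance": None
            if self.abundance is None
            else {
                "index": list(self.abundance.index),
                "columns": list(self.abundance.columns),
                "data": self.abundance.to_numpy().tolist(),
            },
            "pairs": self.pairs,
            "homologous": [list(t) for t in self.homologous],
            "structural": self.structural,
            "de_transcripts": self.de_transcripts,
            "transcripts": self.transcripts,
            "samples": [list(t) for t in self.samples],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruthManifest":
        with open(path) as fh:
            d = json.load(fh)
        ab = d.get("abundance")
        abundance = (
            None
            if ab is None
            else pd.DataFrame(ab["data"], index=ab["index"], columns=ab["columns"])
        )
        return cls(
            mirnas=d["mirnas"],
            abundance=abundance,
            pairs=d["pairs"],
            homologous=[tuple(t) for t in d["homologous"]],
            structural=d["structural"],
            de_transcripts={k: float(v) for k, v in d["de_transcripts"].items()},
            transcripts=d["transcripts"],
            samples=[tuple(t) for t in d["samples"]],
        )


# ---------------------------------------------------------------------------
# stage 1: references
# ---------------------------------------------------------------------------

def generate_references(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> Tuple[Dict[str, str], Dict[str, str], GroundTruthManifest]:
    """Random transcript sets for both species plus structural references.

    ``frac_homologous`` of the fungal transcripts get an identical copy in
    the plant set (overwriting a plant transcript), recorded in the manifest.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    lo, hi = config.transcript_len_range

    def _make(prefix: str, n: int) -> Dict[str, str]:
        return {
            f"{prefix}{i:04d}": _random_rna(rng, int(rng.integers(lo, hi + 1)))
            for i in range(1, n + 1)
        }

    plant = _make("PLT", config.n_transcripts_plant)
    fungus = _make("FGT", config.n_transcripts_fungus)

    manifest = GroundTruthManifest(samples=config.sample_table())
    n_hom = int(round(config.frac_homologous * config.n_transcripts_fungus))
    n_hom = min(n_hom, config.n_transcripts_plant, config.n_transcripts_fungus)
    if n_hom:
        fungal_ids = rng.choice(sorted(fungus), size=n_hom, replace=False)
        plant_ids = rng.choice(sorted(plant), size=n_hom, replace=False)
        for pid, fid in zip(plant_ids, fungal_ids):
            plant[pid] = fungus[fid]
            manifest.homologous.append((pid, fid))

    manifest.structural = [
        _random_rna(rng, config.structural_len) for _ in range(config.n_structural_refs)
    ]
    manifest.transcripts = {t: "plant" for t in plant}
    manifest.transcripts.update({t: "fungus" for t in fungus})
    return plant, fungus, manifest


# ---------------------------------------------------------------------------
# stage 2: miRNAs, planted pairs, planted DE, abundances
# ---------------------------------------------------------------------------

def plant_mirnas_and_targets(
    refs_plant: Dict[str, str],
    refs_fungus: Dict[str, str],
    manifest: GroundTruthManifest,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> GroundTruthManifest:
    """Generate mature miRNAs, embed target sites, and fix per-sample
    abundances.

    Endogenous pairs stay within one species; cross-kingdom pairs link a
    plant miRNA to a fungal transcript (the direction the inference targets).
    Each pair's target transcript carries the exact reverse complement of
    the mature sequence at a recorded position.  miRNAs participating in a
    pair are "responsive": downregulated 2^-mirna_de_log2fc in the wildtype
    interaction and restored to control level in the mutant interaction.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    lo, hi = config.mirna_len_range

    mirna_ids = {"plant": [], "fungus": []}
    for species, n, prefix in (
        ("plant", config.n_mirnas_plant, "pmir"),
        ("fungus", config.n_mirnas_fungus, "fmir"),
    ):
        for i in range(1, n + 1):
            mid = f"{prefix}_{i:02d}"
            base = float(rng.uniform(*config.mirna_base_range))
            manifest.mirnas[mid] = {
                "seq": _random_rna(rng, int(rng.integers(lo, hi + 1))),
                "species": species,
                "responsive": False,
                "base": base,
            }
            mirna_ids[species].append(mid)

    homologous_ids = {t for pair in manifest.homologous for t in pair}
    free = {
        "plant": [t for t in sorted(refs_plant) if t not in homologous_ids],
        "fungus": [t for t in sorted(refs_fungus) if t not in homologous_ids],
    }
    n_endo_fungus = config.n_endogenous_pairs // 2
    n_endo_plant = config.n_endogenous_pairs - n_endo_fungus
    needed = {
        "fungus": config.n_crosskingdom_pairs + n_endo_fungus,
        "plant": n_endo_plant,
    }
    for sp, n in needed.items():
        if n > len(free[sp]):
            raise ConfigurationError(
                f"{n} target transcripts requested for species {sp!r} "
                f"but only {len(free[sp])} are available"
            )

    targets = {
        sp: list(rng.choice(free[sp], size=needed[sp], replace=False)) for sp in needed
    }
    refs = {"plant": refs_plant, "fungus": refs_fungus}

    def _plant_pair(mid: str, tid: str, relationship: str, species_t: str) -> None:
        mature = manifest.mirnas[mid]["seq"]
        site = reverse_complement(mature)
        transcript = refs[species_t][tid]
        if len(transcript) < len(site):
            raise ConfigurationError(f"transcript {tid} shorter than miRNA site")
        start = int(rng.integers(0, len(transcript) - len(site) + 1))
        refs[species_t][tid] = transcript[:start] + site + transcript[start + len(site):]
        manifest.mirnas[mid]["responsive"] = True
        manifest.pairs.append(
            {
                "mirna_id": mid,
                "transcript_id": tid,
                "relationship": relationship,
                "species_of_transcript": species_t,
                "site_start": start,
                "site_end": start + len(site),
                "repression_log2fc": config.repression_log2fc,
            }
        )

    fungal_targets = targets.get("fungus", [])
    for k in range(config.n_crosskingdom_pairs):
        mid = mirna_ids["plant"][k % len(mirna_ids["plant"])]
        _plant_pair(mid, fungal_targets[k], "cross_kingdom", "fungus")
    for k in range(n_endo_fungus):
        mid = mirna_ids["fungus"][k % len(mirna_ids["fungus"])]
        _plant_pair(mid, fungal_targets[config.n_crosskingdom_pairs + k], "endogenous", "fungus")
    plant_targets = targets.get("plant", [])
    offset = config.n_crosskingdom_pairs  # start after the miRNAs used cross-kingdom
    for k in range(n_endo_plant):
        mid = mirna_ids["plant"][(offset + k) % len(mirna_ids["plant"])]
        _plant_pair(mid, plant_targets[k], "endogenous", "plant")

    # planted transcript-level DE, never on target transcripts
    target_ids = {p["transcript_id"] for p in manifest.pairs}
    for species in ("plant", "fungus"):
        candidates = [t for t in free[species] if t not in target_ids]
        n_de = min(config.n_de_transcripts, len(candidates))
        chosen = rng.choice(candidates, size=n_de, replace=False) if n_de else []
        for tid in chosen:
            lfc = float(rng.uniform(*config.de_log2fc_range))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            manifest.de_transcripts[tid] = sign * lfc

    # per-sample expected mature-miRNA copies (the coupling latent)
    samples = [s for s, _ in manifest.samples]
    conditions = dict(manifest.samples)
    # responsive miRNAs: knocked down 2^-d in the wildtype interaction and
    # restored in mutant interactions on an even grid (first mutant fully,
    # later ones partially), mirroring a dcl-deletion series
    mutants = [
        c for c in config.conditions if is_interaction(c) and c != "interaction_wt"
    ]
    condition_mult = {c: 1.0 for c in config.conditions}
    condition_mult["interaction_wt"] = 2.0 ** (-config.mirna_de_log2fc)
    for i, cond in enumerate(mutants):
        condition_mult[cond] = 2.0 ** (-config.mirna_de_log2fc * i / len(mutants))
    abundance = pd.DataFrame(0.0, index=sorted(manifest.mirnas), columns=samples)
    for mid in abundance.index:
        info = manifest.mirnas[mid]
        for sample in samples:
            cond = conditions[sample]
            if info["species"] not in condition_species(cond):
                continue
            mult = condition_mult[cond] if info["responsive"] else 1.0
            noise = 2.0 ** rng.normal(0.0, config.mirna_noise_log2_sd)
            abundance.loc[mid, sample] = info["base"] * mult * noise
    manifest.abundance = abundance
    return manifest


# ---------------------------------------------------------------------------
# stage 3: count matrices
# ---------------------------------------------------------------------------

def simulate_count_matrices(
    manifest: GroundTruthManifest,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[Dict[str, pd.DataFrame], pd.DataFrame]:
    """NB count matrices per species plus a miRNA count table.

    Counts are zero in samples where the feature's species is absent.
    Planted DE transcripts shift their mean by 2^log2FC in interaction
    samples; planted targets follow the coupling model in the module
    docstring; miRNA counts are NB draws around the manifest abundances.
    """
    if config.nb_dispersion <= 0:
        raise ConfigurationError("nb_dispersion must be > 0")
    if manifest.abundance is None:
        raise ValueError("manifest incomplete: run plant_mirnas_and_targets first")
    rng = np.random.default_rng(config.seed) if rng is None else rng

    samples = [s for s, _ in manifest.samples]
    conditions = dict(manifest.samples)
    pairs_by_transcript: Dict[str, List[dict]] = {}
    for p in manifest.pairs:
        pairs_by_transcript.setdefault(p["transcript_id"], []).append(p)

    matrices: Dict[str, pd.DataFrame] = {}
    for species in ("plant", "fungus"):
        features = sorted(t for t, sp in manifest.transcripts.items() if sp == species)
        base = np.exp(
            rng.normal(config.base_mean_log_mu, config.base_mean_log_sigma, len(features))
        )
        mu = np.zeros((len(features), len(samples)))
        for j, sample in enumerate(samples):
            cond = conditions[sample]
            present = species in condition_species(cond)
            interaction = is_interaction(cond)
            for i, tid in enumerate(features):
                if not present:
                    continue
                m = base[i]
                if interaction and tid in manifest.de_transcripts:
                    m *= 2.0 ** manifest.de_transcripts[tid]
                for p in pairs_by_transcript.get(tid, ()):
                    rep = p["repression_log2fc"]
                    if interaction:
                        m *= 2.0 ** rep
                    info = manifest.mirnas[p["mirna_id"]]
                    if info["species"] in condition_species(cond):
                        rel = manifest.abundance.loc[p["mirna_id"], sample] / info["base"]
                        m *= 2.0 ** (-rep * rel)
                mu[i, j] = m
        counts = _nb_draw(rng, mu, config.nb_dispersion)
        matrices[species] = pd.DataFrame(counts, index=features, columns=samples)

    mirna_counts = pd.DataFrame(
        _nb_draw(rng, manifest.abundance.to_numpy(), config.nb_dispersion),
        index=manifest.abundance.index,
        columns=samples,
    )
    return matrices, mirna_counts


# ---------------------------------------------------------------------------
# stage 4: sRNA read pools
# ---------------------------------------------------------------------------

def _mutate_once(rng: np.random.Generator, seq: str) -> str:
    pos = int(rng.integers(len(seq)))
    alternatives = [b for b in "ACGU" if b != seq[pos]]
    return seq[:pos] + alternatives[int(rng.integers(3))] + seq[pos + 1 :]


def simulate_srna_fastq(
    manifest: GroundTruthManifest,
    refs_plant: Mapping[str, str],
    refs_fungus: Mapping[str, str],
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> Dict[str, List[SmallRNARead]]:
    """Per-sample read pools of exactly ``reads_per_sample`` reads.

    Composition per sample (multinomial): structural contaminant windows at
    ``frac_structural``, mature-miRNA copies proportional to the manifest
    abundances (scaled so control-level samples carry about ``frac_mirna`` of
    reads), and transcript degradation fragments (uniform position, both
    strands, lengths spanning the configured range and hence partly outside
    18-32 nt) filling the remainder.  Mature copies carry at most one
    substitution, applied with probability 1-(1-seq_error_rate)^length.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.reads_per_sample
    pools: Dict[str, List[SmallRNARead]] = {}
    if n == 0:
        warnings.warn("reads_per_sample=0: emitting empty read pools")
        return {s: [] for s, _ in manifest.samples}

    mirna_ids = sorted(manifest.mirnas)
    total_base = sum(manifest.mirnas[m]["base"] for m in mirna_ids) or 1.0
    copies_scale = config.frac_mirna * n / total_base
    refs = {"plant": dict(refs_plant), "fungus": dict(refs_fungus)}
    frag_lo, frag_hi = config.fragment_len_range

    for sample, cond in manifest.samples:
        present = condition_species(cond)
        expected = np.zeros(len(mirna_ids) + 2)
        expected[0] = config.frac_structural * n
        for i, mid in enumerate(mirna_ids):
            expected[1 + i] = copies_scale * manifest.abundance.loc[mid, sample]
        if config.frac_mirna < 1.0:
            expected[-1] = max(0.0, n - expected.sum())
        counts = rng.multinomial(n, expected / expected.sum())

        reads: List[SmallRNARead] = []
        for _ in range(counts[0]):
            ref = manifest.structural[int(rng.integers(len(manifest.structural)))]
            length = int(rng.integers(18, 33))
            start = int(rng.integers(0, len(ref) - length + 1))
            reads.append(SmallRNARead(ref[start : start + length], 1, sample))
        for i, mid in enumerate(mirna_ids):
            mature = manifest.mirnas[mid]["seq"]
            p_err = 1.0 - (1.0 - config.seq_error_rate) ** len(mature)
            for _ in range(counts[1 + i]):
                seq = mature
                if config.seq_error_rate > 0 and rng.random() < p_err:
                    seq = _mutate_once(rng, seq)
                reads.append(SmallRNARead(seq, 1, sample))
        source_ids = [
            (sp, tid) for sp in sorted(present) for tid in sorted(refs[sp])
        ]
        for _ in range(counts[-1]):
            sp, tid = source_ids[int(rng.integers(len(source_ids)))]
            transcript = refs[sp][tid]
            length = min(int(rng.integers(frag_lo, frag_hi + 1)), len(transcript))
            start = int(rng.integers(0, len(transcript) - length + 1))
            frag = transcript[start : start + length]
            if rng.random() < 0.5:
                frag = reverse_complement(frag)
            reads.append(SmallRNARead(frag, 1, sample))
        pools[sample] = reads
    return pools


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

@dataclass
class SyntheticExperiment:
    config: SimulationConfig
    refs_plant: Dict[str, str]
    refs_fungus: Dict[str, str]
    manifest: GroundTruthManifest
    counts: Dict[str, pd.DataFrame]
    mirna_counts: pd.DataFrame
    reads: Optional[Dict[str, List[SmallRNARead]]] = None

    @property
    def mirna_catalog(self) -> Dict[str, str]:
        return {m: info["seq"] for m, info in self.manifest.mirnas.items()}


def simulate_experiment(
    config: SimulationConfig, with_reads: bool = True
) -> SyntheticExperiment:
    """Run all generator stages on one RNG stream keyed by ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    plant, fungus, manifest = generate_references(config, rng)
    manifest = plant_mirnas_and_targets(plant, fungus, manifest, config, rng)
    counts, mirna_counts = simulate_count_matrices(manifest, config, rng)
    reads = (
        simulate_srna_fastq(manifest, plant, fungus, config, rng) if with_reads else None
    )
    return SyntheticExperiment(config, plant, fungus, manifest, counts, mirna_counts, reads)
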