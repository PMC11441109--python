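"""Simulation configuration for the two-species toy experiment.

The defaults encode the study design the downstream inference assumes:
three biological replicates per condition; plant and fungus mono-culture
controls plus three interaction conditions — wildtype and two
RNA-silencing-mutant interactions in which responsive miRNA levels are
restored fully and partially (a dcl-deletion series); negative-binomially
distributed counts; planted differential expression with |log2FC| in
[2, 6]; and planted miRNA-target pairs whose repression strength defaults
to 3.0 log2 units.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Tuple

import yaml

#: species present in each condition; interaction conditions carry both
CONTROL_PLANT = "control_plant"
CONTROL_FUNGUS = "control_fungus"
INTERACTION_WT = "interaction_wt"
#: interactions with RNA-silencing mutants: responsive miRNA levels are
#: restored fully in the first mutant and partially in later ones
INTERACTION_MUT1 = "interaction_mut1"
INTERACTION_MUT2 = "interaction_mut2"

DEFAULT_CONDITIONS = (
    CONTROL_PLANT,
    CONTROL_FUNGUS,
    INTERACTION_WT,
    INTERACTION_MUT1,
    INTERACTION_MUT2,
)


def condition_species(condition: str) -> frozenset:
    """Which species are physically present in a condition's samples."""
    if "plant" in condition:
        return frozenset({"plant"})
    if "fungus" in condition:
        return frozenset({"fungus"})
    return frozenset({"plant", "fungus"})


def is_interaction(condition: str) -> bool:
    return len(condition_species(condition)) == 2


class ConfigurationError(ValueError):
    """Raised when a SimulationConfig violates its invariants."""


@dataclass
class SimulationConfig:
    seed: int = 0
    n_transcripts_plant: int = 100
    n_transcripts_fungus: int = 100
    transcript_len_range: Tuple[int, int] = (300, 1500)
    n_samples_per_condition: int = 3
    conditions: Tuple[str, ...] = DEFAULT_CONDITIONS
    nb_dispersion: float = 0.05
    n_mirnas_plant: int = 6
    n_mirnas_fungus: int = 4
    mirna_len_range: Tuple[int, int] = (19, 24)
    n_endogenous_pairs: int = 4
    n_crosskingdom_pairs: int = 5
    repression_log2fc: float = 3.0
    #: log2 downregulation of responsive miRNAs in the wildtype interaction
    mirna_de_log2fc: float = 3.0
    #: planted transcript-level DE (per species), |log2FC| drawn from the range
    n_de_transcripts: int = 10
    de_log2fc_range: Tuple[float, float] = (2.0, 6.0)
    seq_error_rate: float = 0.01
    frac_structural: float = 0.1
    frac_homologous: float = 0.05
    #: control-level fraction of reads originating from mature miRNAs
    frac_mirna: float = 0.25
    reads_per_sample: int = 2000
    n_structural_refs: int = 3
    structural_len: int = 120
    #: expected mature-miRNA copies per sample at control level
    mirna_base_range: Tuple[float, float] = (60.0, 150.0)
    #: log-normal spread of transcript base means (natural-log sigma)
    base_mean_log_mu: float = 5.3
    base_mean_log_sigma: float = 1.0
    #: per-sample log2-normal wobble of miRNA abundances (drives the planted
    #: within-condition anticorrelation)
    mirna_noise_log2_sd: float = 0.5
    #: read-length range of degradation fragments before length filtering
    fragment_len_range: Tuple[int, int] = (16, 34)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        def _interval(name, lo_ok=1):
            lo, hi = getattr(self, name)
            if lo > hi or lo < lo_ok:
                raise ConfigurationError(f"{name} must be a non-empty interval, got {lo, hi}")

        for name in (
            "n_transcripts_plant",
            "n_transcripts_fungus",
            "n_samples_per_condition",
            "n_mirnas_plant",
            "n_mirnas_fungus",
            "n_structural_refs",
            "structural_len",
        ):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        for name in ("n_endogenous_pairs", "n_crosskingdom_pairs", "n_de_transcripts", "reads_per_sample"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        _interval("transcript_len_range")
        _interval("mirna_len_range")
        _interval("fragment_len_range")
        _interval("de_log2fc_range", lo_ok=0)
        _interval("mirna_base_range", lo_ok=0)
        if not (18 <= self.mirna_len_range[0] and self.mirna_len_range[1] <= 32):
            raise ConfigurationError("mirna_len_range must lie within [18, 32]")
        for name in ("seq_error_rate", "frac_structural", "frac_homologous", "frac_mirna"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be a probability in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be > 0")
        if self.repression_log2fc < 0:
            raise ConfigurationError("repression_log2fc must be >= 0")
        if len(set(self.conditions)) != len(self.conditions):
            raise ConfigurationError("conditions must be unique labels")

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in (
            "transcript_len_range",
            "mirna_len_range",
            "de_log2fc_range",
            "mirna_base_range",
            "fragment_len_range",
            "conditions",
        ):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    # -- sample bookkeeping ------------------------------------------------
    def sample_table(self):
        """Ordered (sample_id, condition) pairs for the whole experiment."""
        rows = []
        for cond in self.conditions:
            for r in range(1, self.n_samples_per_condition + 1):
                rows.append((f"{cond}_r{r}", cond))
        return rows

    def samples_of(self, condition: str):
        return [s for s, c in self.sample_table() if c == condition]
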