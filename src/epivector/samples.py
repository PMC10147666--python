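"""Sample metadata: experimental conditions and library descriptors.

A *condition* is the biological context a library was made from —
which AAV capsid delivered the vector, which species/context the cells
came from, and the harvest timepoint. Every chromatin (Cut&Tag) library
targets one chromatin feature (a histone mark, a core histone or Pol II);
each condition additionally carries Tn5 "input" libraries made from bulk
nuclear DNA, which see abundance but no mark-specific enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigurationError

CAPSIDS = ("LK03", "DJ", "AM", "other")
SPECIES = ("human", "mouse")
CONTEXTS = ("cell_line", "liver")
TARGETS = ("H3K4me3", "H3K27ac", "H3K9me3", "H3K27me3",
           "H2A", "H3", "H4", "PolII", "Tn5_input")
ACTIVE_MARKS = ("H3K4me3", "H3K27ac")
REPRESSIVE_MARKS = ("H3K9me3", "H3K27me3")
TN5_INPUT = "Tn5_input"

#: Columns that identify the condition a Tn5 input library normalizes.
#: Deliberately excludes the chromatin target and the replicate: one pool
#: of Tn5 inputs serves every mark profiled in that condition.
CONDITION_KEY = ("species", "context", "capsid", "timepoint")


@dataclass(frozen=True)
class Condition:
    """Experimental condition: capsid x species x context x timepoint."""

    capsid: str
    species: str
    context: str = "cell_line"
    timepoint: str = "day3"

    def __post_init__(self):
        if self.capsid not in CAPSIDS:
            raise ConfigurationError(f"unknown capsid {self.capsid!r}")
        if self.species not in SPECIES:
            raise ConfigurationError(f"unknown species {self.species!r}")
        if self.context not in CONTEXTS:
            raise ConfigurationError(f"unknown context {self.context!r}")

    def key(self) -> tuple:
        return (self.species, self.context, self.capsid, self.timepoint)

    def label(self) -> str:
        return f"{self.capsid}-{self.species}-{self.context}-{self.timepoint}"


@dataclass(frozen=True)
class LibraryMeta:
    """Identity of one sequencing library."""

    sample_id: str
    condition: Condition
    target: str
    replicate: int = 1
    total_fragments: int = 0

    def __post_init__(self):
        if self.target not in TARGETS:
            raise ConfigurationError(f"unknown target {self.target!r}")
        if self.replicate < 1:
            raise ConfigurationError("replicate index must be >= 1")

    @property
    def is_input(self) -> bool:
        return self.target == TN5_INPUT
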