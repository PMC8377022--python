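"""Taxonomic lineages and the asterisk naming convention for unclassified taxa.

A lineage is an ordered run of rank names from kingdom down to genus.  A taxon
may be classified only part of the way down; at any requested rank below its
resolution it is displayed as its nearest classified ancestor suffixed with a
single ``*`` (e.g. an OTU classified only to the family Enterobacteriaceae
appears as ``Enterobacteriaceae*`` in a genus-level table).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

RANKS: tuple[str, ...] = ("kingdom", "phylum", "class", "order", "family", "genus")

_PREFIXES = {"k__", "p__", "c__", "o__", "f__", "g__", "d__", "s__"}


def _clean(segment: str) -> str | None:
    seg = segment.strip()
    if seg[:3].lower() in _PREFIXES:
        seg = seg[3:]
    seg = seg.strip()
    if not seg or seg.lower() in {"unclassified", "unknown", "na"}:
        return None
    return seg


@dataclass(frozen=True)
class TaxonLineage:
    """Ordered taxonomic labels, kingdom -> genus; ``None`` marks unclassified.

    Invariant: once a rank is unclassified every lower rank is too.
    """

    names: tuple[str | None, ...]

    def __post_init__(self) -> None:
        if len(self.names) > len(RANKS):
            raise ValueError(f"lineage deeper than {RANKS[-1]}: {self.names}")
        seen_gap = False
        for name in self.names:
            if name is None:
                seen_gap = True
            elif seen_gap:
                raise ValueError(f"classified rank below an unclassified one: {self.names}")

    @classmethod
    def from_string(cls, lineage: str, sep: str = ";") -> "TaxonLineage":
        names = tuple(_clean(s) for s in lineage.split(sep))
        # trailing all-None segments are padding, keep at least one entry
        while len(names) > 1 and names[-1] is None and names[-2] is None:
            names = names[:-1]
        return cls(names)

    def __str__(self) -> str:
        return ";".join(n if n is not None else "" for n in self.names)

    @property
    def depth(self) -> int:
        """Number of classified ranks."""
        return sum(n is not None for n in self.names)

    def name_at(self, rank: str) -> str | None:
        i = RANKS.index(rank)
        if i >= len(self.names):
            return None
        return self.names[i]

    def label_at(self, rank: str) -> str:
        """Display label at ``rank``: the classified name, or nearest classified
        ancestor with an asterisk."""
        i = RANKS.index(rank)
        if i < len(self.names) and self.names[i] is not None:
            return self.names[i]
        for name in reversed(self.names[:i]):
            if name is not None:
                return name + "*"
        raise ValueError(f"lineage has no classified rank at or above {rank}: {self}")

    def truncate(self, rank: str) -> "TaxonLineage":
        i = RANKS.index(rank)
        names = self.names[: i + 1]
        if len(names) < i + 1:
            names = names + (None,) * (i + 1 - len(names))
        return TaxonLineage(names)

    @cached_property
    def display_name(self) -> str:
        """Label at the lineage's deepest covered rank."""
        return self.label_at(RANKS[len(self.names) - 1])
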