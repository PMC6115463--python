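"""Linear-motif representation and phosphosite-to-kinase substrate mapping.

A phosphosite is summarised by the 15-residue window centred on the
phosphorylated S/T/Y (seven flanking residues on each side, ``_``-padded at
protein termini).  A linear motif is a position-specific constraint over
that window: each of the 15 slots either allows any residue (``X``) or a
specific set of residues; the centre slot is restricted to a non-empty
subset of {S, T, Y}.  Matching a window against a library of kinase,
phosphatase and SH2 motifs yields, per motif, the set of putative
substrate sites used downstream for kinase-set enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .errors import ValidationError

logger = logging.getLogger(__name__)

WINDOW = 15
HALF = WINDOW // 2
CENTER_RESIDUES = frozenset("STY")
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PAD = "_"

MOTIF_CATEGORIES = ("kinase", "phosphatase", "sh2")


@dataclass(frozen=True)
class Motif:
    """A position-specific linear motif over a 15-residue window.

    ``slots[i]`` is either ``None`` (wildcard ``X``, matches anything
    including terminal padding) or a frozenset of allowed residues.  The
    centre slot (index 7) must be a non-empty subset of {S, T, Y}.
    """

    name: str
    category: str
    slots: tuple

    def __post_init__(self):
        if self.category not in MOTIF_CATEGORIES:
            raise ValidationError(
                f"motif {self.name!r}: unknown category {self.category!r}"
            )
        if len(self.slots) != WINDOW:
            raise ValidationError(
                f"motif {self.name!r}: pattern length {len(self.slots)} != {WINDOW}"
            )
        center = self.slots[HALF]
        if center is None or not center or not center <= CENTER_RESIDUES:
            raise ValidationError(
                f"motif {self.name!r}: center slot must be a non-empty subset of S/T/Y"
            )
        for i, slot in enumerate(self.slots):
            if slot is not None and not slot:
                raise ValidationError(f"motif {self.name!r}: empty slot {i}")

    def pattern_string(self) -> str:
        """Render slots in library-TSV form, e.g. ``X`` or ``RK``."""
        return "\t".join(
            "X" if s is None else "".join(sorted(s)) for s in self.slots
        )


@dataclass
class MotifLibrary:
    """Named collection of motifs with unique names."""

    motifs: list = field(default_factory=list)

    def __post_init__(self):
        names = [m.name for m in self.motifs]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValidationError(f"duplicate motif names: {sorted(dupes)}")
        self._by_name = {m.name: m for m in self.motifs}

    def __len__(self):
        return len(self.motifs)

    def __iter__(self):
        return iter(self.motifs)

    def __getitem__(self, name: str) -> Motif:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def names(self):
        return [m.name for m in self.motifs]

    def counts(self) -> dict:
        out = {c: 0 for c in MOTIF_CATEGORIES}
        for m in self.motifs:
            out[m.category] += 1
        return out


@dataclass(frozen=True)
class KinaseSet:
    """A motif's substrate set: the site ids whose windows match it."""

    kinase: str
    substrates: frozenset

    @property
    def size(self) -> int:
        return len(self.substrates)


def extract_flank(protein_seq: str, position: int, residue: str) -> str:
    """Return the 15-char window centred on ``position`` (1-based).

    The residue at ``position`` must equal ``residue``; windows running
    past either protein terminus are padded with ``_``.
    """
    if not 1 <= position <= len(protein_seq):
        raise ValidationError(
            f"position {position} outside sequence of length {len(protein_seq)}"
        )
    actual = protein_seq[position - 1]
    if actual != residue:
        raise ValidationError(
            f"residue mismatch at position {position}: sequence has {actual!r}, "
            f"annotation says {residue!r}"
        )
    i = position - 1
    left = protein_seq[max(0, i - HALF):i]
    right = protein_seq[i + 1:i + 1 + HALF]
    return PAD * (HALF - len(left)) + left + residue + right + PAD * (HALF - len(right))


def match_motif(window: str, motif: Motif) -> bool:
    """True iff every slot constraint admits the corresponding window residue.

    Wildcard slots match anything; terminal padding ``_`` satisfies only
    wildcard slots.
    """
    if len(window) != WINDOW:
        raise ValidationError(f"window length {len(window)} != {WINDOW}")
    for ch, slot in zip(window, motif.slots):
        if slot is None:
            continue
        if ch not in slot:  # PAD is never a member of a constraint set
            return False
    return True


def build_kinase_sets(sites, library: MotifLibrary, min_size: int = 5,
                      max_size: int = 500) -> list:
    """Match every site window against every motif and return substrate sets.

    ``sites`` is a :class:`~kinasign.io.SiteMatrix` (or anything exposing an
    ``annotations`` frame with a ``flank`` column indexed by site id).  One
    :class:`KinaseSet` is produced per motif whose substrate count lies in
    ``[min_size, max_size]``; excluded motifs are counted in a log message.
    """
    if len(library) == 0:
        raise ValidationError("empty motif library")
    flanks = sites.annotations["flank"]
    sets = []
    n_excluded = 0
    for motif in library:
        members = frozenset(
            site_id for site_id, window in flanks.items()
            if match_motif(window, motif)
        )
        if min_size <= len(members) <= max_size:
            sets.append(KinaseSet(kinase=motif.name, substrates=members))
        else:
            n_excluded += 1
    if n_excluded:
        logger.warning(
            "excluded %d motif sets outside size bounds [%d, %d]",
            n_excluded, min_size, max_size,
        )
    if not sets:
        logger.warning("no motif set within size bounds; empty result")
    return sets
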