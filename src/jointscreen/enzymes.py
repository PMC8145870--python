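"""Restriction enzymes and site finding.

Only the three enzymes used for directional cloning into the pU11L4 multiple
cloning site are built in (NcoI, NotI, NheI); additional enzymes can be
declared programmatically or in a run config, as long as they are palindromic
5'-overhang cutters with an unambiguous recognition sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._seq import clean_seq, revcomp
from .errors import SequenceError, UncloneableGeneError


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A type II restriction enzyme producing a 5' overhang.

    ``cut_top`` and ``cut_bottom`` are 0-based offsets within the recognition
    site: the top strand is cut after ``cut_top`` bases and the bottom strand
    opposite position ``cut_bottom``, so ``recognition[cut_top:cut_bottom]``
    is the single-stranded 5' overhang left on the downstream fragment.
    """

    name: str
    recognition: str
    cut_top: int
    cut_bottom: int

    def __post_init__(self) -> None:
        seq = clean_seq(self.recognition, name=f"{self.name} recognition site")
        object.__setattr__(self, "recognition", seq)
        if not (0 <= self.cut_top < self.cut_bottom <= len(seq)):
            raise ValueError(
                f"{self.name}: cut offsets must satisfy "
                "0 <= cut_top < cut_bottom <= site length (5' overhang)"
            )

    @property
    def site_length(self) -> int:
        return len(self.recognition)

    @property
    def overhang(self) -> str:
        """The 5' overhang sequence regenerated at every ligation joint."""
        return self.recognition[self.cut_top : self.cut_bottom]

    @property
    def is_palindromic(self) -> bool:
        return self.recognition == revcomp(self.recognition)


NCOI = RestrictionEnzyme("NcoI", "CCATGG", 1, 5)
NOTI = RestrictionEnzyme("NotI", "GCGGCCGC", 2, 6)
NHEI = RestrictionEnzyme("NheI", "GCTAGC", 1, 5)

BUILTIN_ENZYMES = {enz.name: enz for enz in (NCOI, NOTI, NHEI)}


def find_sites(seq: str, enzyme: RestrictionEnzyme, circular: bool = False) -> list[int]:
    """0-based start positions of every recognition-site occurrence in ``seq``.

    On a circular sequence occurrences spanning the origin are reported at
    their (mod-length) start position.  Input must be unambiguous ACGT; a
    non-ACGT character raises :class:`SequenceError` naming the offset.
    """
    s = clean_seq(seq)
    site = enzyme.recognition
    search = s + s[: len(site) - 1] if circular else s
    positions: list[int] = []
    i = search.find(site)
    while i != -1:
        positions.append(i)
        i = search.find(site, i + 1)
    return [p for p in positions if p < len(s)]


def select_enzyme_pair(
    insert_coding_seq: str,
) -> tuple[RestrictionEnzyme, RestrictionEnzyme]:
    """Choose the cloning enzyme pair for a gene from its coding sequence.

    The default pair is (NcoI, NotI); if the coding sequence carries an
    internal NcoI site the fallback pair (NheI, NotI) is used instead.  A
    gene with an internal NotI site, or with internal sites for both NcoI
    and NheI, cannot be cloned with the built-in pairs.
    """
    s = clean_seq(insert_coding_seq, name="insert coding sequence")
    if find_sites(s, NOTI):
        raise UncloneableGeneError(
            "internal NotI site: uncloneable with built-in pairs"
        )
    if not find_sites(s, NCOI):
        return (NCOI, NOTI)
    if not find_sites(s, NHEI):
        return (NHEI, NOTI)
    raise UncloneableGeneError(
        "internal NcoI and NheI sites: uncloneable with built-in pairs"
    )
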