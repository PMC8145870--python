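"""Directional restriction cloning model and junction-probe generation.

A gene is PCR-amplified with enzyme-site tails, double digested together
with the vector, and ligated into the vector's multiple cloning site.  The
two ligation points (left joint: vector -> insert; right joint: insert ->
vector) are unique to each correctly assembled recombinant, so a short
window spanning each joint — ``vector_flank_len`` bases of vector plus
``insert_flank_len`` bases of insert — is diagnostic of successful ligation
of that particular gene.  Each recombinant yields four such probes (two
joints x two strands); sequencing reads containing a probe are the
"joint-reads" the downstream screen counts.

Coordinates are 0-based, half-open, on the forward strand; circular
sequences are indexed modulo their length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._seq import circular_slice, clean_seq, revcomp
from .enzymes import RestrictionEnzyme, find_sites
from .errors import DesignError, ProbeCollisionError

MIN_FLANK = 15
MAX_FLANK = 25
DEFAULT_FLANK = 20

#: Fixed probe order; read counting gives earlier probes priority.
PROBE_ORDER = (
    ("left", "forward"),
    ("left", "reverse"),
    ("right", "forward"),
    ("right", "reverse"),
)


@dataclass
class GeneInsert:
    """A PCR fragment carrying one gene, including its enzyme-site tails."""

    gene_id: str
    fragment_seq: str
    enzyme_pair: tuple[RestrictionEnzyme, RestrictionEnzyme] | None = None

    def __post_init__(self) -> None:
        self.fragment_seq = clean_seq(
            self.fragment_seq, name=f"fragment of {self.gene_id}"
        )


@dataclass
class CloningDesign:
    """Vector plus enzyme pair plus the insert set of one pooled experiment.

    ``enzyme_5p``/``enzyme_3p`` is the default pair; an individual insert may
    override it (the NheI fallback for NcoI-containing genes).
    """

    vector_seq: str
    enzyme_5p: RestrictionEnzyme
    enzyme_3p: RestrictionEnzyme
    inserts: list[GeneInsert] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.vector_seq = clean_seq(self.vector_seq, name="vector")
        seen: set[str] = set()
        for ins in self.inserts:
            if ins.gene_id in seen:
                raise DesignError(f"duplicate gene_id {ins.gene_id!r}")
            seen.add(ins.gene_id)

    def pair_for(self, insert: GeneInsert) -> tuple[RestrictionEnzyme, RestrictionEnzyme]:
        return insert.enzyme_pair or (self.enzyme_5p, self.enzyme_3p)


@dataclass
class Recombinant:
    """A correctly ligated circular plasmid.

    ``left_joint_pos``/``right_joint_pos`` are the indices of the first base
    3' of each ligation point on the forward strand, so the insert-derived
    segment is ``seq[left_joint_pos:right_joint_pos]``.
    """

    gene_id: str
    seq: str
    left_joint_pos: int
    right_joint_pos: int

    @property
    def insert_length(self) -> int:
        return self.right_joint_pos - self.left_joint_pos


@dataclass(frozen=True)
class JointProbe:
    gene_id: str
    joint_side: str  # "left" | "right"
    strand: str  # "forward" | "reverse"
    sequence: str
    vector_flank_len: int
    insert_flank_len: int


@dataclass
class JointProbeSet:
    """The four junction-covering probes of one gene, in :data:`PROBE_ORDER`."""

    gene_id: str
    probes: list[JointProbe]

    def __post_init__(self) -> None:
        if len(self.probes) != 4:
            raise DesignError(f"{self.gene_id}: a probe set has exactly 4 probes")
        order = [(p.joint_side, p.strand) for p in self.probes]
        if tuple(order) != PROBE_ORDER:
            raise DesignError(f"{self.gene_id}: probes out of canonical order")

    def sequences(self) -> list[str]:
        return [p.sequence for p in self.probes]


def _single_site(
    seq: str, enzyme: RestrictionEnzyme, circular: bool, what: str
) -> int:
    sites = find_sites(seq, enzyme, circular=circular)
    if len(sites) != 1:
        raise DesignError(
            f"{what} must carry exactly one {enzyme.name} site, found {len(sites)}"
        )
    return sites[0]


def build_recombinant(design: CloningDesign, insert: GeneInsert) -> Recombinant:
    """Assemble the correctly ligated plasmid for one insert.

    The vector is opened at its (unique) site for each enzyme of the pair,
    the insert fragment is trimmed at its own two sites, and the compatible
    5' overhangs are rejoined.  Because vector and insert are cut by the
    same enzyme at each joint, the full recognition site is regenerated:
    the forward strand around a joint reads vector bases + recognition site
    + insert bases.
    """
    e5, e3 = design.pair_for(insert)
    if e5.overhang == "" or e3.overhang == "":  # pragma: no cover - enzymes validated
        raise DesignError("blunt cutters are not supported")
    if e5.recognition == e3.recognition:
        raise DesignError("5' and 3' enzymes must differ (directional cloning)")

    vec = design.vector_seq
    p5 = _single_site(vec, e5, circular=True, what="vector")
    p3 = _single_site(vec, e3, circular=True, what="vector")
    # Linearize the circle so both sites are intact and the 5' site precedes
    # the 3' site; the arc between them (the MCS stuffer) is discarded.
    if not (p5 < p3 and p3 + e3.site_length <= len(vec)):
        vec = vec[p5:] + vec[:p5]
        p5 = 0
        p3 = _single_site(vec, e3, circular=False, what="vector")

    frag = insert.fragment_seq
    if len(frag) < e5.site_length + e3.site_length + 1:
        raise DesignError(
            f"insert {insert.gene_id}: fragment shorter than both recognition "
            "sites plus one base (zero-length insert region)"
        )
    i5 = _single_site(frag, e5, circular=False, what=f"insert {insert.gene_id}")
    i3 = _single_site(frag, e3, circular=False, what=f"insert {insert.gene_id}")
    if i3 < i5 + e5.site_length:
        raise DesignError(
            f"insert {insert.gene_id}: {e3.name} site must lie 3' of the "
            f"{e5.name} site (zero-length insert region)"
        )

    core = frag[i5 + e5.cut_top : i3 + e3.cut_top]
    if not core:
        raise DesignError(f"insert {insert.gene_id}: empty insert region")
    left = p5 + e5.cut_top
    seq = vec[:left] + core + vec[p3 + e3.cut_top :]
    return Recombinant(
        gene_id=insert.gene_id,
        seq=seq,
        left_joint_pos=left,
        right_joint_pos=left + len(core),
    )


def make_joint_probes(
    rec: Recombinant,
    gene_id: str | None = None,
    vector_flank_len: int = DEFAULT_FLANK,
    insert_flank_len: int = DEFAULT_FLANK,
) -> JointProbeSet:
    """Derive the four junction probes of a recombinant.

    A probe spans a joint with ``vector_flank_len`` vector bases and
    ``insert_flank_len`` insert bases; both must lie in [15, 25].  If the
    insert is shorter than the requested insert flank the flank shrinks to
    the available length, but never below 15 bases — below that the probe
    would risk matching other molecules.
    """
    gene_id = gene_id or rec.gene_id
    for val, side in ((vector_flank_len, "vector"), (insert_flank_len, "insert")):
        if not (MIN_FLANK <= val <= MAX_FLANK):
            raise DesignError(
                f"{side} flank length {val} outside [{MIN_FLANK}, {MAX_FLANK}]"
            )
    avail = rec.insert_length
    eff_insert_flank = min(insert_flank_len, avail)
    if eff_insert_flank < MIN_FLANK:
        raise ProbeCollisionError(
            f"{gene_id}: insert provides only {avail} bases of usable flank "
            f"(< {MIN_FLANK}): probe collision risk"
        )

    seq, L, R = rec.seq, rec.left_joint_pos, rec.right_joint_pos
    left_fwd = circular_slice(seq, L - vector_flank_len, L + eff_insert_flank)
    right_fwd = circular_slice(seq, R - eff_insert_flank, R + vector_flank_len)

    def probe(side: str, strand: str, s: str) -> JointProbe:
        return JointProbe(
            gene_id=gene_id,
            joint_side=side,
            strand=strand,
            sequence=s,
            vector_flank_len=vector_flank_len,
            insert_flank_len=eff_insert_flank,
        )

    return JointProbeSet(
        gene_id=gene_id,
        probes=[
            probe("left", "forward", left_fwd),
            probe("left", "reverse", revcomp(left_fwd)),
            probe("right", "forward", right_fwd),
            probe("right", "reverse", revcomp(right_fwd)),
        ],
    )


def build_probe_sets(
    design: CloningDesign,
    vector_flank_len: int = DEFAULT_FLANK,
    insert_flank_len: int = DEFAULT_FLANK,
) -> dict[str, JointProbeSet]:
    """Recombinants and probes for every insert, with a design-wide
    uniqueness check.

    Any probe occurring in more than one gene's set, or occurring anywhere in
    the empty (uncut, circular) vector on either strand, would mis-assign
    read counts and is a hard error.
    """
    sets: dict[str, JointProbeSet] = {}
    owner: dict[str, str] = {}
    vec = design.vector_seq
    vec_scan = vec + vec[:MAX_FLANK * 2]  # circular scan window
    vec_scan_rc = revcomp(vec_scan)
    for insert in design.inserts:
        rec = build_recombinant(design, insert)
        pset = make_joint_probes(
            rec, vector_flank_len=vector_flank_len, insert_flank_len=insert_flank_len
        )
        for p in pset.probes:
            if p.sequence in owner and owner[p.sequence] != insert.gene_id:
                raise ProbeCollisionError(
                    f"probe shared by {owner[p.sequence]} and {insert.gene_id}: "
                    f"{p.sequence}"
                )
            if p.sequence in vec_scan or p.sequence in vec_scan_rc:
                raise ProbeCollisionError(
                    f"{insert.gene_id}: probe occurs in the empty vector: {p.sequence}"
                )
            owner[p.sequence] = insert.gene_id
        sets[insert.gene_id] = pset
    return sets


def build_recombinants(design: CloningDesign) -> dict[str, Recombinant]:
    """Recombinant plasmids for every insert of a design."""
    return {ins.gene_id: build_recombinant(design, ins) for ins in design.inserts}
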