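"""Synthetic pooled-screen generator with known ground truth.

The simulator emulates the three stochastic layers of the pooled screen:

1. **Ligation** — each gene's molecule abundance in the pooled ligation
   mixture is log-normal, ``exp(Normal(0, ligation_dispersion))``.  Equimolar
   ligations in practice show large per-gene efficiency differences (roughly
   a 50-fold spread between the best- and worst-ligating fragments), which a
   log-scale SD of about 0.8 reproduces; dispersion 0 gives the idealized
   equal-share pool.
2. **Transformation** — ``n_transformants`` cells each take up
   ``1 + Poisson(cotransformation_rate)`` plasmids drawn from the pool with
   replacement.  Every plasmid carries its gene's survival probability; the
   cell lives only if each plasmid either passes its own Bernoulli(survival)
   check or is rescued because the same cell carries a plasmid listed as
   that gene's antitoxin.  Surviving cells contribute all their plasmids to
   the transformant pool — this is the mechanism that lets a toxic gene ride
   along with its antitoxin and show a deceptively high depletion ratio.
3. **Sequencing** — paired-end reads from fragments drawn gene-
   proportionally; fragment length Normal(insert_size_mean, insert_size_sd)
   truncated at the read length, start uniform on the circular plasmid,
   random strand.  With probability ``plasmid_side_bias`` a fragment that
   overlaps a ligation joint is re-anchored so its 5' end sits on the
   vector side of that joint, reproducing the library-prep strand bias seen
   for short inserts.  Sequencing errors are independent substitutions.

All randomness flows from ``SimConfig.seed`` through ``numpy`` generators;
a fixed seed gives bit-identical pools, reads, and reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import revcomp
from .cloning import (
    DEFAULT_FLANK as _FLANK,
    CloningDesign,
    GeneInsert,
    JointProbeSet,
    Recombinant,
    build_probe_sets,
    build_recombinants,
)
from .counting import JointCountTable, count_joint_reads
from .enzymes import BUILTIN_ENZYMES, NCOI, NOTI, find_sites, select_enzyme_pair
from .errors import ConfigError, JointScreenError
from .screen import (
    DEFAULT_THRESHOLD,
    CALL_TOXIC,
    ScreenResult,
    results_to_frame,
    screen_counts,
)

_BASES = "ACGT"


@dataclass
class SimGene:
    """Ground truth for one gene: its PCR fragment and survival factor.

    ``survival`` is the probability that a cell transformed with this gene's
    plasmid (alone) survives; 1 = non-toxic, 0 = absolutely toxic.
    """

    gene_id: str
    fragment_seq: str
    survival: float = 1.0
    enzyme_5p: str | None = None  # "NcoI" | "NheI"; 3' enzyme is always NotI

    def __post_init__(self) -> None:
        if not (0.0 <= self.survival <= 1.0):
            raise ConfigError(f"{self.gene_id}: survival must be in [0, 1]")
        if self.enzyme_5p is not None and self.enzyme_5p not in ("NcoI", "NheI"):
            raise ConfigError(f"{self.gene_id}: enzyme_5p must be NcoI or NheI")


@dataclass
class SimConfig:
    """Full specification of a simulated pooled screen."""

    genes: list[SimGene]
    ligation_dispersion: float = 0.8
    n_transformants: int = 100_000
    cotransformation_rate: float = 0.0
    antitoxin_map: dict[str, str] = field(default_factory=dict)
    reads_per_sample: int = 100_000
    read_length: int = 150
    insert_size_mean: int = 625
    insert_size_sd: int = 311
    plasmid_side_bias: float = 0.0
    error_rate: float = 0.001
    seed: int = 0
    excluded_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.genes:
            raise ConfigError("at least one gene required")
        if self.ligation_dispersion < 0:
            raise ConfigError("ligation_dispersion must be >= 0")
        if self.n_transformants < 1:
            raise ConfigError("n_transformants must be >= 1")
        if self.cotransformation_rate < 0:
            raise ConfigError("cotransformation_rate must be >= 0")
        if self.reads_per_sample < 0:
            raise ConfigError("reads_per_sample must be >= 0")
        if not (0.0 <= self.plasmid_side_bias < 1.0):
            raise ConfigError("plasmid_side_bias must be in [0, 1)")
        if not (0.0 <= self.error_rate < 1.0):
            raise ConfigError("error_rate must be in [0, 1)")
        if self.insert_size_mean < self.read_length:
            raise ConfigError(
                "insert_size_mean below read_length: fragments cannot carry a read"
            )
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ConfigError("duplicate gene_id in simulation config")
        for tox, anti in self.antitoxin_map.items():
            if tox not in ids or anti not in ids:
                raise ConfigError(f"antitoxin pair ({tox}, {anti}) names unknown genes")

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]


@dataclass
class PoolState:
    """Per-gene molecule abundance at one stage of the screen."""

    gene_ids: list[str]
    abundance: np.ndarray
    stage: str  # "ligation" | "transformant"

    def __post_init__(self) -> None:
        self.abundance = np.asarray(self.abundance, dtype=float)
        if (self.abundance < 0).any():
            raise JointScreenError("abundances must be non-negative")
        if not (self.abundance > 0).any():
            raise JointScreenError("pool is empty: no positive abundance")

    @property
    def shares(self) -> np.ndarray:
        return self.abundance / self.abundance.sum()


# ---------------------------------------------------------------------------
# synthetic design generation


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def _scrub_sites(seq: str, enzymes, rng: np.random.Generator, circular=False) -> str:
    """Mutate single bases until no recognition site of ``enzymes`` remains."""
    s = list(seq)
    for _ in range(200):
        text = "".join(s)
        hits = []
        for enz in enzymes:
            hits.extend((p, enz) for p in find_sites(text, enz, circular=circular))
        if not hits:
            return text
        for pos, enz in hits:
            off = (pos + int(rng.integers(0, enz.site_length))) % len(s)
            cur = s[off]
            s[off] = _BASES[(_BASES.index(cur) + 1 + int(rng.integers(0, 3))) % 4]
    raise JointScreenError("failed to scrub restriction sites from random sequence")


def synthetic_vector(
    rng: np.random.Generator, backbone_len: int = 3000, stuffer_len: int = 12
) -> str:
    """A circular cloning vector with an NcoI / NheI / NotI multiple cloning
    site and a site-free random backbone."""
    enzymes = list(BUILTIN_ENZYMES.values())
    backbone = _scrub_sites(_random_seq(rng, backbone_len), enzymes, rng)
    sp1 = _scrub_sites(_random_seq(rng, stuffer_len), enzymes, rng)
    sp2 = _scrub_sites(_random_seq(rng, stuffer_len), enzymes, rng)
    mcs = "CCATGG" + sp1 + "GCTAGC" + sp2 + "GCGGCCGC"
    vec = backbone + mcs
    # junction-spanning sites would break the one-site invariant
    for enz in enzymes:
        if len(find_sites(vec, enz, circular=True)) != 1:
            return synthetic_vector(rng, backbone_len, stuffer_len)
    return vec


def synthetic_fragment(
    rng: np.random.Generator, coding_len: int, tail_len: int = 4
) -> tuple[str, str]:
    """A PCR fragment plus the name of its 5' cloning enzyme.

    The enzyme pair follows the cloning rule (NcoI/NotI, or NheI/NotI when
    the coding sequence happens to contain an NcoI site), so a realistic
    minority of genes exercises the fallback pair.
    """
    coding = _scrub_sites(_random_seq(rng, coding_len), [NOTI], rng)
    try:
        e5, e3 = select_enzyme_pair(coding)
    except JointScreenError:
        # both NcoI and NheI present: scrub NheI so the NheI/NotI pair applies
        coding = _scrub_sites(coding, [BUILTIN_ENZYMES["NheI"]], rng)
        e5, e3 = select_enzyme_pair(coding)
    frag = (
        _random_seq(rng, tail_len)
        + e5.recognition
        + coding
        + e3.recognition
        + _random_seq(rng, tail_len)
    )
    # tails may create extra sites by chance; regenerate if so
    if len(find_sites(frag, e5)) != 1 or len(find_sites(frag, e3)) != 1:
        return synthetic_fragment(rng, coding_len, tail_len)
    return frag, e5.name


def make_sim_config(
    n_genes: int = 24,
    toxic: Mapping[str, float] | Sequence[str] | None = None,
    seed: int = 0,
    coding_len_range: tuple[int, int] = (250, 900),
    **kwargs,
) -> SimConfig:
    """Convenience constructor: random gene fragments plus a toxicity map.

    ``toxic`` maps gene ids (``g01`` ... ``gNN``) to survival factors, or is
    a sequence of gene ids given survival 0.01.  Remaining keyword arguments
    are passed to :class:`SimConfig`.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xD1CE]))
    if toxic is None:
        toxic = {}
    elif not isinstance(toxic, Mapping):
        toxic = {g: 0.01 for g in toxic}
    genes = []
    for i in range(1, n_genes + 1):
        gid = f"g{i:02d}"
        clen = int(rng.integers(coding_len_range[0], coding_len_range[1] + 1))
        frag, e5_name = synthetic_fragment(rng, clen)
        genes.append(
            SimGene(
                gene_id=gid,
                fragment_seq=frag,
                survival=float(toxic.get(gid, 1.0)),
                enzyme_5p=e5_name,
            )
        )
    unknown = set(toxic) - {g.gene_id for g in genes}
    if unknown:
        raise ConfigError(f"toxic map names unknown genes: {sorted(unknown)}")
    return SimConfig(genes=genes, seed=seed, **kwargs)


def design_from_config(config: SimConfig, rng: np.random.Generator) -> CloningDesign:
    """Build the cloning design implied by a simulation config.

    The vector is synthesized deterministically from ``rng``.  Each gene's
    5' enzyme comes from its ``enzyme_5p`` field when set; otherwise it is
    inferred as NcoI when the fragment carries exactly one NcoI site and
    NheI otherwise (an explicit field is preferred, since an NheI-cloned
    fragment legitimately retains an internal NcoI site).
    """
    inserts = []
    for g in config.genes:
        frag = g.fragment_seq
        if g.enzyme_5p is not None:
            e5 = BUILTIN_ENZYMES[g.enzyme_5p]
        elif len(find_sites(frag, NCOI)) == 1:
            e5 = NCOI
        else:
            e5 = BUILTIN_ENZYMES["NheI"]
        inserts.append(
            GeneInsert(gene_id=g.gene_id, fragment_seq=frag, enzyme_pair=(e5, NOTI))
        )
    return CloningDesign(
        vector_seq=synthetic_vector(rng),
        enzyme_5p=NCOI,
        enzyme_3p=NOTI,
        inserts=inserts,
    )


# ---------------------------------------------------------------------------
# pool stages


def simulate_ligation_pool(
    config: SimConfig, rng: np.random.Generator | None = None
) -> PoolState:
    """Draw per-gene abundances of the pooled ligation mixture.

    Abundance is ``exp(Normal(0, ligation_dispersion))`` per gene; dispersion
    0 yields exactly equal abundances.  Genes listed in
    ``config.excluded_genes`` are present with abundance 0 (the mixture was
    lost or omitted from the pool — they become dropouts downstream).
    """
    rng = rng or np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = len(config.genes)
    if config.ligation_dispersion == 0:
        abundance = np.ones(n)
    else:
        abundance = np.exp(rng.normal(0.0, config.ligation_dispersion, size=n))
    for gid in config.excluded_genes:
        abundance[config.gene_ids.index(gid)] = 0.0
    return PoolState(config.gene_ids, abundance, "ligation")


def simulate_transformation(
    pool: PoolState, config: SimConfig, rng: np.random.Generator | None = None
) -> PoolState:
    """Transform the ligation pool and apply toxin selection.

    See the module docstring for the survival/rescue model.  Returns plasmid
    counts contributed by surviving cells.
    """
    if pool.stage != "ligation":
        raise JointScreenError("transformation expects a ligation-stage pool")
    rng = rng or np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    shares = pool.shares
    n_genes = len(shares)
    survival = np.array([g.survival for g in config.genes])
    n_cells = config.n_transformants

    if config.cotransformation_rate == 0:
        cell_gene = rng.choice(n_genes, size=n_cells, p=shares)
        counts = np.bincount(cell_gene, minlength=n_genes)
        survivors = rng.binomial(counts, survival)
        return PoolState(pool.gene_ids, survivors.astype(float), "transformant")

    idx_of = {g: i for i, g in enumerate(pool.gene_ids)}
    anti_idx = {idx_of[t]: idx_of[a] for t, a in config.antitoxin_map.items()}
    k = 1 + rng.poisson(config.cotransformation_rate, size=n_cells)
    total = int(k.sum())
    draws = rng.choice(n_genes, size=total, p=shares)
    passes = rng.random(total) < survival[draws]
    bounds = np.concatenate([[0], np.cumsum(k)])
    out = np.zeros(n_genes, dtype=float)
    for c in range(n_cells):
        lo, hi = bounds[c], bounds[c + 1]
        cell = draws[lo:hi]
        ok = passes[lo:hi]
        if ok.all():
            alive = True
        else:
            cell_set = set(cell.tolist())
            alive = all(
                ok[j] or anti_idx.get(cell[j], -1) in cell_set
                for j in range(len(cell))
            )
        if alive:
            np.add.at(out, cell, 1.0)
    if not (out > 0).any():
        raise JointScreenError("no transformant survived: empty transformant pool")
    return PoolState(pool.gene_ids, out, "transformant")


# ---------------------------------------------------------------------------
# read simulation


def _mutate_reads(
    reads: list[str], error_rate: float, rng: np.random.Generator
) -> list[str]:
    if error_rate <= 0 or not reads:
        return reads
    read_len = len(reads[0])
    n_err = rng.binomial(read_len, error_rate, size=len(reads))
    for i in np.nonzero(n_err)[0]:
        s = list(reads[i])
        for _ in range(n_err[i]):
            pos = int(rng.integers(0, len(s)))
            s[pos] = _BASES[(_BASES.index(s[pos]) + 1 + int(rng.integers(0, 3))) % 4]
        reads[i] = "".join(s)
    return reads


def simulate_reads(
    pool: PoolState,
    recombinants: Mapping[str, Recombinant],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[tuple[str, str]]:
    """Draw paired-end reads from the recombinant plasmids of a pool.

    Returns ``reads_per_sample`` (mate1, mate2) sequence pairs; mate2 is the
    reverse complement of the fragment's far end, as in a standard FR
    library.  Deterministic given ``rng``.
    """
    rng = rng or np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    n = config.reads_per_sample
    if n == 0:
        return []
    missing = [g for g in pool.gene_ids if g not in recombinants]
    if missing:
        raise JointScreenError(f"no recombinant sequence for genes {missing}")
    rl = config.read_length

    gene_ids = pool.gene_ids
    shares = pool.shares
    gidx = rng.choice(len(gene_ids), size=n, p=shares)
    lengths = np.rint(
        rng.normal(config.insert_size_mean, config.insert_size_sd, size=n)
    ).astype(np.int64)
    np.clip(lengths, rl, None, out=lengths)
    u_start = rng.random(n)
    reverse = rng.random(n) < 0.5
    bias_roll = rng.random(n)
    u_anchor = rng.random(n)

    doubled = {}
    plen = {}
    joints = {}
    for g in gene_ids:
        rec = recombinants[g]
        if len(rec.seq) < rl:
            raise ConfigError(
                f"recombinant {g} ({len(rec.seq)} bp) shorter than the read length"
            )
        doubled[g] = rec.seq + rec.seq
        plen[g] = len(rec.seq)
        joints[g] = (rec.left_joint_pos, rec.right_joint_pos)

    pairs: list[tuple[str, str]] = []
    for i in range(n):
        g = gene_ids[gidx[i]]
        pl = plen[g]
        length = min(int(lengths[i]), pl)
        start = int(u_start[i] * pl)
        rev = bool(reverse[i])
        L, R = joints[g]
        if config.plasmid_side_bias > 0 and bias_roll[i] < config.plasmid_side_bias:
            over_left = (L - start) % pl < length
            over_right = (R - start) % pl < length
            if over_left or over_right:
                # re-anchor: 5' end on the vector side, close enough that the
                # first mate reads across the joint from the vector into the
                # insert (the library-prep bias this knob emulates)
                u = _FLANK + int(u_anchor[i] * (rl - 2 * _FLANK + 1))
                if over_left:
                    start = (L - u) % pl
                    rev = False
                else:
                    start = (R + u - length) % pl
                    rev = True
        dseq = doubled[g]
        head = dseq[start : start + rl]
        tail = dseq[start + length - rl : start + length]
        if rev:
            pairs.append((revcomp(tail), head))
        else:
            pairs.append((head, revcomp(tail)))

    if config.error_rate > 0:
        flat = [r for p in pairs for r in p]
        flat = _mutate_reads(flat, config.error_rate, rng)
        pairs = [(flat[2 * i], flat[2 * i + 1]) for i in range(n)]
    return pairs


# ---------------------------------------------------------------------------
# end-to-end harness


@dataclass
class EndToEndResult:
    design: CloningDesign
    probe_sets: dict[str, JointProbeSet]
    ligation_pool: PoolState
    transformant_pool: PoolState
    ligation_counts: JointCountTable
    plasmid_counts: JointCountTable
    screen_results: list[ScreenResult]
    truth: pd.DataFrame
    confusion: dict
    ligation_reads: list[tuple[str, str]]
    plasmid_reads: list[tuple[str, str]]


def run_end_to_end(
    config: SimConfig,
    threshold: float = DEFAULT_THRESHOLD,
    toxic_truth_threshold: float = 0.5,
) -> EndToEndResult:
    """Simulate both arms of the screen and run the full analysis pipeline.

    Chains ligation pool -> transformation -> paired-end reads for both
    sample arms -> joint-read counting -> depletion screen, then compares
    each gene's call against its ground-truth survival (truth label "toxic"
    when survival < ``toxic_truth_threshold``).
    """
    ss = np.random.SeedSequence([config.seed, 0xE2E])
    rng_design, rng_lig, rng_trans, rng_rlig, rng_rplas = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    design = design_from_config(config, rng_design)
    recombinants = build_recombinants(design)
    probe_sets = build_probe_sets(design)

    lig_pool = simulate_ligation_pool(config, rng_lig)
    trans_pool = simulate_transformation(lig_pool, config, rng_trans)

    lig_reads = simulate_reads(lig_pool, recombinants, config, rng_rlig)
    plas_reads = simulate_reads(trans_pool, recombinants, config, rng_rplas)

    lig_counts = count_joint_reads(lig_reads, probe_sets, sample_id="sim-ligation")
    plas_counts = count_joint_reads(plas_reads, probe_sets, sample_id="sim-plasmid")

    results = screen_counts([(lig_counts, plas_counts)], threshold=threshold)

    truth_rows = []
    tp = fp = fn = tn = 0
    by_id = {r.gene_id: r for r in results}
    for g in config.genes:
        r = by_id[g.gene_id]
        is_toxic = g.survival < toxic_truth_threshold
        called = r.call == CALL_TOXIC
        if is_toxic and called:
            tp += 1
        elif is_toxic:
            fn += 1
        elif called:
            fp += 1
        else:
            tn += 1
        truth_rows.append(
            {
                "gene_id": g.gene_id,
                "survival": g.survival,
                "truth_toxic": is_toxic,
                "ligation_share": float(
                    lig_pool.abundance[config.gene_ids.index(g.gene_id)]
                    / lig_pool.abundance.sum()
                ),
                "ratio": np.nan if r.ratio is None else r.ratio,
                "call": r.call,
            }
        )
    confusion = {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "tn": tn,
        "n_candidates": tp + fp,
        "threshold": threshold,
    }
    return EndToEndResult(
        design=design,
        probe_sets=probe_sets,
        ligation_pool=lig_pool,
        transformant_pool=trans_pool,
        ligation_counts=lig_counts,
        plasmid_counts=plas_counts,
        screen_results=results,
        truth=pd.DataFrame(truth_rows),
        confusion=confusion,
        ligation_reads=lig_reads,
        plasmid_reads=plas_reads,
    )


def screen_frame(result: EndToEndResult) -> pd.DataFrame:
    return results_to_frame(result.screen_results)
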