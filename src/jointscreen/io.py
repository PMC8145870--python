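"""File formats: FASTA, FASTQ(.gz), TSV reports, sample sheets, configs.

All tabular outputs are tab-separated with a header row, UTF-8, no index
column.  Gzipped FASTQ is handled transparently by file suffix; gzip output
is written with a zeroed timestamp so identical runs produce byte-identical
files.
"""

from __future__ import annotations

import gzip
import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .cloning import (
    DEFAULT_FLANK,
    CloningDesign,
    GeneInsert,
    JointProbe,
    JointProbeSet,
    PROBE_ORDER,
)
from .counting import PROBE_COLUMNS, JointCountTable, ReadSample
from .enzymes import BUILTIN_ENZYMES, NCOI, NOTI, find_sites
from .errors import (
    ConfigError,
    DesignError,
    FastaFormatError,
    FastqFormatError,
    JointScreenError,
)
from .simulate import SimConfig, SimGene


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a (multi-)FASTA file as (record id, sequence) tuples.

    Line wrapping is irrelevant; sequences are returned unmodified (case
    preserved) so callers decide on validation.
    """
    path = Path(path)
    try:
        records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    except (ValueError, UnicodeDecodeError) as exc:
        raise FastaFormatError(f"{path}: malformed FASTA ({exc})") from exc
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# FASTQ


def _open_text(path: Path) -> _stdio.TextIOBase:
    if path.suffix == ".gz":
        return _stdio.TextIOWrapper(gzip.open(path, "rb"))
    return path.open("r")


def iter_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Stream (title, sequence, quality) records from FASTQ or FASTQ.gz.

    A truncated or malformed file raises :class:`FastqFormatError` naming
    the file and the index of the offending record.
    """
    path = Path(path)
    n = 0
    try:
        with _open_text(path) as fh:
            for title, seq, qual in FastqGeneralIterator(fh):
                yield title, seq, qual
                n += 1
    except (ValueError, EOFError, OSError) as exc:
        raise FastqFormatError(f"{path}: record {n}: {exc}") from exc


def iter_fastq_pairs(
    r1_path: str | Path, r2_path: str | Path
) -> Iterator[tuple[str, str]]:
    """Stream mate sequence pairs from two FASTQ files; mate counts must match."""
    it1 = iter_fastq(r1_path)
    it2 = iter_fastq(r2_path)
    sentinel = object()
    n = 0
    while True:
        a = next(it1, sentinel)
        b = next(it2, sentinel)
        if a is sentinel and b is sentinel:
            return
        if a is sentinel or b is sentinel:
            short = r1_path if a is sentinel else r2_path
            raise FastqFormatError(
                f"mismatched mate counts: {short} ended at record {n}"
            )
        yield a[1], b[1]
        n += 1


def iter_sample_reads(sample: ReadSample) -> Iterator[str]:
    """All read sequences of a sample; paired mates interleaved (R1, R2, ...)."""
    if sample.r2_path is None:
        for _, seq, _ in iter_fastq(sample.r1_path):
            yield seq
    else:
        for s1, s2 in iter_fastq_pairs(sample.r1_path, sample.r2_path):
            yield s1
            yield s2


def write_fastq(
    records: Iterable[tuple[str, str, str]], path: str | Path
) -> None:
    """Write (title, seq, qual) records; ``.gz`` suffix selects gzip with a
    zeroed mtime for reproducible bytes."""
    path = Path(path)
    buf = _stdio.StringIO()
    for title, seq, qual in records:
        buf.write(f"@{title}\n{seq}\n+\n{qual}\n")
    data = buf.getvalue().encode()
    if path.suffix == ".gz":
        with path.open("wb") as raw:
            with gzip.GzipFile(fileobj=raw, mode="wb", mtime=0, filename="") as gz:
                gz.write(data)
    else:
        path.write_bytes(data)


# ---------------------------------------------------------------------------
# TSV


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# probe tables


def probes_to_frame(probe_sets: Mapping[str, JointProbeSet]) -> pd.DataFrame:
    rows = []
    for gene, pset in probe_sets.items():
        for p in pset.probes:
            rows.append(
                {
                    "gene_id": gene,
                    "joint_side": p.joint_side,
                    "strand": p.strand,
                    "sequence": p.sequence,
                    "vector_flank_len": p.vector_flank_len,
                    "insert_flank_len": p.insert_flank_len,
                }
            )
    return pd.DataFrame(rows)


def frame_to_probe_sets(df: pd.DataFrame) -> dict[str, JointProbeSet]:
    sets: dict[str, JointProbeSet] = {}
    for gene, grp in df.groupby("gene_id", sort=False):
        by_key = {
            (r.joint_side, r.strand): JointProbe(
                gene_id=gene,
                joint_side=r.joint_side,
                strand=r.strand,
                sequence=r.sequence,
                vector_flank_len=int(r.vector_flank_len),
                insert_flank_len=int(r.insert_flank_len),
            )
            for r in grp.itertuples()
        }
        try:
            probes = [by_key[key] for key in PROBE_ORDER]
        except KeyError as exc:
            raise DesignError(f"probe table: gene {gene} missing probe {exc}") from exc
        sets[gene] = JointProbeSet(gene_id=gene, probes=probes)
    return sets


def write_probe_fasta(probe_sets: Mapping[str, JointProbeSet], path: str | Path) -> None:
    records = []
    for gene, pset in probe_sets.items():
        for p in pset.probes:
            records.append((f"{gene}|{p.joint_side}|{p.strand}", p.sequence))
    write_fasta(records, path)


def write_count_table(table: JointCountTable, path: str | Path) -> None:
    write_tsv(table.to_frame(), path)


def read_count_table(path: str | Path, sample_id: str | None = None) -> JointCountTable:
    df = read_tsv(path)
    missing = {"gene_id", *PROBE_COLUMNS} - set(df.columns)
    if missing:
        raise JointScreenError(f"{path}: count table missing columns {sorted(missing)}")
    return JointCountTable.from_frame(df, sample_id or Path(path).stem)


# ---------------------------------------------------------------------------
# sample sheet


def read_sample_sheet(path: str | Path) -> list[ReadSample]:
    """Parse the sample sheet (sample_id, kind, replicate, batch, r1_path,
    r2_path) and check its invariants."""
    df = read_tsv(path)
    required = {"sample_id", "kind", "replicate", "batch", "r1_path"}
    missing = required - set(df.columns)
    if missing:
        raise JointScreenError(f"{path}: sample sheet missing columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise JointScreenError(f"{path}: duplicate sample_id {dupes}")
    samples = []
    for row in df.itertuples():
        r2 = getattr(row, "r2_path", None)
        if pd.isna(r2):
            r2 = None
        samples.append(
            ReadSample(
                sample_id=str(row.sample_id),
                sample_kind=str(row.kind),
                r1_path=str(row.r1_path),
                r2_path=None if r2 is None else str(r2),
                replicate=int(row.replicate),
                batch=str(row.batch),
            )
        )
    lig_batches = {s.batch for s in samples if s.sample_kind == "ligation"}
    for s in samples:
        if s.sample_kind == "plasmid" and s.batch not in lig_batches:
            raise JointScreenError(
                f"{path}: plasmid sample {s.sample_id} has no ligation sample "
                f"in batch {s.batch!r}"
            )
    return samples


# ---------------------------------------------------------------------------
# configs


@dataclass
class RunConfig:
    """Pipeline-wide knobs shared by the CLI subcommands."""

    vector_flank_len: int = DEFAULT_FLANK
    insert_flank_len: int = DEFAULT_FLANK
    max_mismatches: int = 0
    threshold: float = 0.5
    control_gene: str = "g178"
    dedupe_pairs: bool = False
    seed: int = 0
    output_dir: str = "."
    per_gene_enzyme: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.max_mismatches < 0:
            raise ConfigError("max_mismatches must be >= 0")
        if self.threshold < 0:
            raise ConfigError("threshold must be >= 0")
        for gene, enz in self.per_gene_enzyme.items():
            if enz not in BUILTIN_ENZYMES:
                raise ConfigError(f"unknown enzyme {enz!r} for gene {gene!r}")


def load_run_config(path: str | Path | None) -> RunConfig:
    if path is None:
        return RunConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: run config must be a mapping")
    try:
        return RunConfig(**data)
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def load_sim_config(path: str | Path, seed: int | None = None) -> SimConfig:
    """Load a simulation config from YAML.

    Either an explicit ``genes`` list (gene_id, fragment_seq, survival,
    enzyme_5p) or ``n_genes`` plus an optional ``toxic`` map for synthetic
    fragments.  A ``seed`` argument overrides the file's seed.
    """
    from .simulate import make_sim_config  # deferred: io <-> simulate

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: simulation config must be a mapping")
    if seed is not None:
        data["seed"] = int(seed)
    try:
        if "genes" in data:
            genes = [SimGene(**g) for g in data.pop("genes")]
            return SimConfig(genes=genes, **data)
        n_genes = int(data.pop("n_genes", 24))
        toxic = data.pop("toxic", None)
        sim_seed = int(data.pop("seed", 0))
        return make_sim_config(n_genes=n_genes, toxic=toxic, seed=sim_seed, **data)
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# design assembly from files


def infer_enzyme_pair(fragment_seq: str):
    """Heuristic enzyme pair for a tailed PCR fragment read from FASTA.

    NcoI/NotI when the fragment carries exactly one NcoI site, else
    NheI/NotI when it carries exactly one NheI site.  Ambiguous fragments
    (an NheI-cloned gene with an internal NcoI site looks identical to an
    NcoI-cloned gene with an internal NheI site) need an explicit per-gene
    override in the run config.
    """
    if len(find_sites(fragment_seq, NCOI)) == 1:
        return (NCOI, NOTI)
    if len(find_sites(fragment_seq, BUILTIN_ENZYMES["NheI"])) == 1:
        return (BUILTIN_ENZYMES["NheI"], NOTI)
    raise DesignError(
        "cannot infer enzyme pair from fragment sites; "
        "declare per_gene_enzyme in the run config"
    )


def design_from_files(
    vector_path: str | Path,
    inserts_path: str | Path,
    per_gene_enzyme: Mapping[str, str] | None = None,
) -> CloningDesign:
    """Build a cloning design from a vector FASTA and an insert multi-FASTA.

    Insert record ids are the gene ids.  ``per_gene_enzyme`` maps gene id to
    the name of its 5' enzyme when the heuristic inference is ambiguous.
    """
    vec_records = read_fasta(vector_path)
    if len(vec_records) != 1:
        raise DesignError(f"{vector_path}: vector FASTA must hold exactly one record")
    per_gene_enzyme = per_gene_enzyme or {}
    inserts = []
    for gene_id, seq in read_fasta(inserts_path):
        if gene_id in per_gene_enzyme:
            pair = (BUILTIN_ENZYMES[per_gene_enzyme[gene_id]], NOTI)
        else:
            pair = infer_enzyme_pair(seq.upper())
        inserts.append(GeneInsert(gene_id=gene_id, fragment_seq=seq, enzyme_pair=pair))
    return CloningDesign(
        vector_seq=vec_records[0][1],
        enzyme_5p=NCOI,
        enzyme_3p=NOTI,
        inserts=inserts,
    )
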