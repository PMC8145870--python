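"""Independent brute-force oracles used to cross-check the implementation.

These deliberately share no code with the package: plain nested loops over
every offset of every read, and naive O(n*m) site scanning.
"""

from __future__ import annotations


def naive_find_sites(seq: str, site: str, circular: bool = False) -> list[int]:
    """Positions of ``site`` in ``seq`` by testing every offset."""
    text = seq + seq[: len(site) - 1] if circular else seq
    hits = []
    for i in range(len(seq)):
        if i + len(site) <= len(text) and text[i : i + len(site)] == site:
            hits.append(i)
    return hits


def hamming_occurs(read: str, probe: str, k: int) -> bool:
    for off in range(len(read) - len(probe) + 1):
        if sum(a != b for a, b in zip(read[off : off + len(probe)], probe)) <= k:
            return True
    return False


def brute_force_counts(
    reads: list[str],
    probes_by_gene: dict[str, list[str]],
    max_mismatches: int = 0,
    min_len: int | None = None,
):
    """Reference joint-read counting: every probe at every offset of every
    read; first matching probe (in list order) wins per gene.

    Returns (counts dict gene -> [4 ints], multi_gene_reads, skipped).
    """
    if min_len is None:
        min_len = max(
            (len(p) for ps in probes_by_gene.values() for p in ps), default=0
        )
    counts = {g: [0, 0, 0, 0] for g in probes_by_gene}
    multi = 0
    skipped = 0
    for read in reads:
        if len(read) < min_len:
            skipped += 1
            continue
        genes_hit = 0
        for gene, probes in probes_by_gene.items():
            for pi, probe in enumerate(probes):
                if hamming_occurs(read, probe, max_mismatches):
                    counts[gene][pi] += 1
                    genes_hit += 1
                    break
        if genes_hit >= 2:
            multi += 1
    return counts, multi, skipped
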