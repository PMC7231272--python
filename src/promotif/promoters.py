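"""Strand-aware promoter window extraction and promoter-set containers.

Coordinates are 0-based, half-open throughout.  The default window covers
1000 bp upstream and 100 bp downstream of a transcription start site; the
downstream stretch includes the TSS base itself, so the window spans exactly
``upstream + downstream`` bases.  For a minus-strand gene the genomic interval
``[tss - downstream + 1, tss + upstream + 1)`` is extracted and
reverse-complemented so that position 0 of every returned sequence is its
most-upstream base.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._seqs import revcomp

logger = logging.getLogger(__name__)

DEFAULT_UPSTREAM = 1000
DEFAULT_DOWNSTREAM = 100


@dataclass(frozen=True)
class TssRecord:
    """A transcription start site: gene, chromosome, 0-based coordinate, strand."""

    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"{self.gene_id}: negative TSS {self.tss}")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")


@dataclass
class PromoterSet:
    """An ordered set of promoter sequences with their genomic provenance.

    ``intervals`` holds (chrom, start, end, strand) per promoter when the set
    came from a genome; synthetic sets leave it ``None``.
    """

    ids: list[str]
    sequences: list[str]
    intervals: list[tuple[str, int, int, str]] | None = None
    upstream: int | None = None
    downstream: int | None = None

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise ValueError("ids and sequences length mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate gene ids in promoter set")
        self.sequences = [s.upper() for s in self.sequences]

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self):
        return iter(zip(self.ids, self.sequences))

    def encoded(self) -> tuple[np.ndarray, np.ndarray]:
        """Cached int8 code matrix + true lengths (sequences are treated as immutable)."""
        cached = getattr(self, "_encoded", None)
        if cached is None:
            from ._seqs import encode_batch
            cached = encode_batch(self.sequences)
            object.__setattr__(self, "_encoded", cached)
        return cached

    @property
    def total_bp(self) -> int:
        return sum(len(s) for s in self.sequences)

    def sequence(self, gene_id: str) -> str:
        return self.sequences[self.ids.index(gene_id)]

    def subset(self, gene_ids: Sequence[str]) -> "PromoterSet":
        index = {g: i for i, g in enumerate(self.ids)}
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise KeyError(f"genes without promoters: {missing[:5]}")
        rows = [index[g] for g in gene_ids]
        return PromoterSet(
            ids=[self.ids[i] for i in rows],
            sequences=[self.sequences[i] for i in rows],
            intervals=None if self.intervals is None else [self.intervals[i] for i in rows],
            upstream=self.upstream,
            downstream=self.downstream,
        )

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for i, (gid, seq) in enumerate(self):
                desc = ""
                if self.intervals is not None:
                    c, s, e, st = self.intervals[i]
                    desc = f" {c}:{s}-{e}({st})"
                fh.write(f">{gid}{desc}\n{seq}\n")

    @classmethod
    def from_fasta(cls, path) -> "PromoterSet":
        ids: list[str] = []
        seqs: list[str] = []
        cur: list[str] = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip()
                if line.startswith(">"):
                    if ids:
                        seqs.append("".join(cur))
                    ids.append(line[1:].split()[0])
                    cur = []
                elif line:
                    cur.append(line)
        if ids:
            seqs.append("".join(cur))
        return cls(ids=ids, sequences=seqs)


def read_tss_table(path) -> list[TssRecord]:
    """Read a 4-column TSV (gene, chrom, tss, strand) or BED6 file of TSS records."""
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) >= 6 and parts[1].isdigit() and parts[5] in "+-":
                # BED6: chrom start end name score strand; TSS is the strand-aware 5' end
                chrom, start, end, name, _, strand = parts[:6]
                tss = int(start) if strand == "+" else int(end) - 1
                records.append(TssRecord(name, chrom, tss, strand))
            elif len(parts) >= 4:
                gene, chrom, tss, strand = parts[:4]
                records.append(TssRecord(gene, chrom, int(tss), strand))
            else:
                raise ValueError(f"unparseable TSS line: {line!r}")
    return records


def extract_promoters(genome: Mapping[str, object], tss_table: Iterable[TssRecord],
                      upstream: int = DEFAULT_UPSTREAM,
                      downstream: int = DEFAULT_DOWNSTREAM) -> PromoterSet:
    """Extract strand-aware promoter windows around each TSS.

    ``genome`` maps chromosome name to an indexable sequence (a dict of
    strings or a ``pyfaidx.Fasta``).  Windows running off a chromosome end are
    clipped with a logged warning.  A gene appearing more than once keeps its
    first record (warned); an unknown chromosome is an error naming the record.
    """
    ids: list[str] = []
    seqs: list[str] = []
    intervals: list[tuple[str, int, int, str]] = []
    seen: set[str] = set()
    for rec in tss_table:
        if rec.gene_id in seen:
            logger.warning("duplicate TSS for %s: first record wins", rec.gene_id)
            continue
        if rec.chrom not in genome:
            raise KeyError(f"unknown chromosome {rec.chrom!r} for gene {rec.gene_id}")
        chrom_seq = genome[rec.chrom]
        chrom_len = len(chrom_seq)
        if rec.strand == "+":
            start, end = rec.tss - upstream, rec.tss + downstream
        else:
            start, end = rec.tss - downstream + 1, rec.tss + upstream + 1
        cstart, cend = max(start, 0), min(end, chrom_len)
        if (cstart, cend) != (start, end):
            logger.warning("window for %s clipped to [%d, %d)", rec.gene_id, cstart, cend)
        seq = str(chrom_seq[cstart:cend]).upper()
        if rec.strand == "-":
            seq = revcomp(seq)
        seen.add(rec.gene_id)
        ids.append(rec.gene_id)
        seqs.append(seq)
        intervals.append((rec.chrom, cstart, cend, rec.strand))
    return PromoterSet(ids=ids, sequences=seqs, intervals=intervals,
                       upstream=upstream, downstream=downstream)


def sample_reference(universe: Sequence[TssRecord], k: int = 5000,
                     exclude: set[str] | None = None, seed: int = 0) -> list[TssRecord]:
    """Sample ``k`` distinct TSS records uniformly without replacement.

    Genes in ``exclude`` (typically the analysed clusters) are removed first.
    """
    exclude = exclude or set()
    pool = [r for r in universe if r.gene_id not in exclude]
    if len(pool) < k:
        raise ValueError(f"universe too small: {len(pool)} eligible < k={k}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=k, replace=False)
    return [pool[i] for i in idx]
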