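"""Cross-species conservation of promoter motifs on a multiple alignment.

Each species' ungapped promoter is scanned for motifs at its calibrated
threshold; hits are lifted into alignment-column space through per-species
coordinate maps, and hit windows from different species are merged when their
column intervals overlap or fall within a tolerance.  A motif is *positionally
conserved* when a single merged window contains a hit from every species that
carries the motif at all — the alignment-overlay analogue of judging "same
localization" on a promoter alignment figure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import AlignIO, Phylo

from .motifs import PWM, MotifHit, scan


def species_order_from_tree(path, species: Sequence[str]) -> list[str]:
    """Leaf order of a newick tree, restricted to the given species.

    Used purely to order report rows phylogenetically; species missing from
    the tree keep their original relative order at the end.
    """
    tree = Phylo.read(path, "newick")
    leaf_order = [leaf.name for leaf in tree.get_terminals() if leaf.name]
    known = [sp for sp in leaf_order if sp in set(species)]
    return known + [sp for sp in species if sp not in set(known)]


@dataclass
class AlignmentBlock:
    """Aligned ortholog promoters with gapped<->ungapped coordinate maps."""

    species: list[str]
    rows: list[str]                  # gapped sequences, equal length
    columns_of: dict[str, np.ndarray] = field(init=False)  # ungapped pos -> column

    def __post_init__(self) -> None:
        if len(self.species) < 2:
            raise ValueError("alignment needs at least 2 sequences")
        if len(set(len(r) for r in self.rows)) != 1:
            raise ValueError("ragged alignment: unequal gapped lengths")
        if len(set(self.species)) != len(self.species):
            raise ValueError("duplicate species ids in alignment")
        self.rows = [r.upper() for r in self.rows]
        self.columns_of = {
            sp: np.array([i for i, ch in enumerate(row) if ch != "-"], dtype=np.int64)
            for sp, row in zip(self.species, self.rows)
        }

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def ungapped(self, species: str) -> str:
        return self.rows[self.species.index(species)].replace("-", "")

    def to_column(self, species: str, position: int) -> int:
        """Alignment column of an ungapped position in this species."""
        return int(self.columns_of[species][position])


def read_alignment(path) -> AlignmentBlock:
    """Read an aligned FASTA or Clustal file, preserving species order."""
    with open(path) as fh:
        head = fh.read(30)
    fmt = "clustal" if head.lstrip().upper().startswith("CLUSTAL") else "fasta"
    aln = AlignIO.read(path, fmt)
    return AlignmentBlock(species=[rec.id for rec in aln],
                          rows=[str(rec.seq) for rec in aln])


def map_hits_to_columns(hits: Sequence[MotifHit], block: AlignmentBlock,
                        species: str, motif_length: int) -> list[tuple[int, int]]:
    """Map each hit to its inclusive alignment-column interval.

    Gaps inside the motif in *other* species do not affect the interval; gaps
    inserted into this species' row simply stretch the interval across them.
    """
    cols = block.columns_of[species]
    out = []
    for h in hits:
        if h.offset + motif_length > cols.size:
            raise IndexError(f"hit at {h.offset} beyond ungapped length {cols.size}")
        out.append((int(cols[h.offset]), int(cols[h.offset + motif_length - 1])))
    return out


def _merge_windows(intervals: list[tuple[int, int, str]], tolerance: int
                   ) -> list[tuple[int, int, frozenset]]:
    """Merge species-tagged column intervals that overlap or lie within tolerance."""
    merged: list[tuple[int, int, set]] = []
    for start, end, sp in sorted(intervals):
        if merged and start - merged[-1][1] <= tolerance:
            last = merged[-1]
            merged[-1] = (last[0], max(last[1], end), last[2] | {sp})
        else:
            merged.append((start, end, {sp}))
    return [(s, e, frozenset(sp)) for s, e, sp in merged]


@dataclass
class ConservationReport:
    """Presence and positional conservation of motifs across aligned orthologs."""

    species: list[str]
    presence: pd.DataFrame                 # species x matrix booleans
    windows: dict[str, list[tuple[int, int, frozenset]]]  # per matrix, column windows
    localized: dict[str, bool]             # one window covers every carrying species
    conserved_in_all: dict[str, bool]      # present and co-localized in every species

    def window_table(self) -> pd.DataFrame:
        rows = [
            {"matrix_id": m, "col_start": s, "col_end": e,
             "species": ",".join(sorted(sp))}
            for m, wins in self.windows.items() for s, e, sp in wins
        ]
        return pd.DataFrame(rows, columns=["matrix_id", "col_start", "col_end", "species"])


def conservation_matrix(block: AlignmentBlock, pwms: Sequence[PWM],
                        thresholds: Mapping[str, float],
                        window_merge_tolerance: int = 10) -> ConservationReport:
    """Scan every species for every motif and summarise presence and localization."""
    presence = pd.DataFrame(False, index=list(block.species),
                            columns=[p.matrix_id for p in pwms])
    windows: dict[str, list] = {}
    localized: dict[str, bool] = {}
    conserved_all: dict[str, bool] = {}
    for pwm in pwms:
        thr = thresholds[pwm.matrix_id]
        tagged: list[tuple[int, int, str]] = []
        for sp in block.species:
            hits = scan(block.ungapped(sp), pwm, thr, promoter_id=sp)
            presence.loc[sp, pwm.matrix_id] = len(hits) > 0
            for iv in map_hits_to_columns(hits, block, sp, len(pwm)):
                tagged.append((iv[0], iv[1], sp))
        wins = _merge_windows(tagged, window_merge_tolerance)
        windows[pwm.matrix_id] = wins
        carriers = frozenset(sp for sp in block.species if presence.loc[sp, pwm.matrix_id])
        loc = bool(carriers) and any(carriers <= sp_set for _, _, sp_set in wins)
        localized[pwm.matrix_id] = loc
        conserved_all[pwm.matrix_id] = loc and carriers == frozenset(block.species)
    return ConservationReport(species=list(block.species), presence=presence,
                              windows=windows, localized=localized,
                              conserved_in_all=conserved_all)
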