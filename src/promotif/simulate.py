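"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the data a promoter-regulation study consumes without
any downloads: background promoter sets with motif sites planted at controlled
per-promoter probabilities, log2 expression matrices with block-correlated
gene modules and per-condition effects, ortholog promoter alignments with
scripted motif gain/loss along a species order, and qPCR Ct tables with known
fold changes and replicate noise.  Everything is driven by integer seeds; one
root seed spawns independent child streams per operation so stages can be
re-run in isolation and reproduce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from ._seqs import BASES, decode, encode, revcomp
from .conservation import AlignmentBlock
from .motifs import PWM, scan
from .promoters import PromoterSet

UNIFORM = (0.25, 0.25, 0.25, 0.25)


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent child seeds (< 2**31) from one root seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Study-scale parameters for the promoter-enrichment simulation.

    Defaults mirror the promoter-window study design the pipeline targets:
    1100 bp windows (1000 bp upstream + 100 bp downstream of the TSS), a
    5000-promoter reference set, and a uniform base composition.
    """

    seed: int = 0
    n_target_promoters: int = 200
    n_reference_promoters: int = 5000
    promoter_length: int = 1100
    background_composition: tuple[float, float, float, float] = UNIFORM
    plant_probability: float = 0.5
    sites_per_promoter: int | Mapping[int, float] = 1
    strand_probability: float = 0.5

    def __post_init__(self) -> None:
        comp = np.asarray(self.background_composition, dtype=float)
        if comp.shape != (4,) or (comp < 0).any() or abs(comp.sum() - 1.0) > 1e-9:
            raise ValueError(f"invalid background composition {self.background_composition}")
        for name in ("plant_probability", "strand_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.promoter_length < 1:
            raise ValueError("promoter_length must be positive")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "background_composition" in raw:
            raw["background_composition"] = tuple(raw["background_composition"])
        return cls(**raw)


@dataclass(frozen=True)
class PlantRecord:
    promoter_id: str
    matrix_id: str
    offset: int
    strand: str


@dataclass
class PlantLog:
    """Exhaustive record of every planted motif site."""

    records: list[PlantRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records],
                            columns=["promoter_id", "matrix_id", "offset", "strand"])


# ---------------------------------------------------------------------------
# Promoters and motif planting
# ---------------------------------------------------------------------------

def gen_background_promoters(n: int, length: int,
                             composition: Sequence[float] = UNIFORM,
                             seed: int = 0, prefix: str = "prom") -> PromoterSet:
    """``n`` i.i.d. background promoter sequences of the given length."""
    comp = np.asarray(composition, dtype=float)
    if length <= 0:
        raise ValueError("length must be positive")
    if comp.shape != (4,) or (comp < 0).any() or abs(comp.sum() - 1.0) > 1e-9:
        raise ValueError(f"invalid composition {composition}")
    rng = np.random.default_rng(seed)
    if np.allclose(comp, 0.25):
        draws = rng.integers(0, 4, size=(n, length)).astype(np.int8)
    else:
        # inverse-CDF sampling: much faster than rng.choice with probabilities
        draws = np.searchsorted(np.cumsum(comp / comp.sum()),
                                rng.random((n, length)), side="right").astype(np.int8)
        np.clip(draws, 0, 3, out=draws)
    width = max(len(str(max(n - 1, 0))), 4)
    ids = [f"{prefix}{i:0{width}d}" for i in range(n)]
    return PromoterSet(ids=ids, sequences=[decode(row) for row in draws])


def _draw_site_count(rng: np.random.Generator,
                     spec: int | Mapping[int, float]) -> int:
    if isinstance(spec, (int, np.integer)):
        return int(spec)
    ks = sorted(spec)
    ps = np.array([spec[k] for k in ks], dtype=float)
    return int(rng.choice(ks, p=ps / ps.sum()))


def plant_motifs(promoters: PromoterSet, pwm: PWM, plant_probability: float,
                 sites_per_promoter: int | Mapping[int, float] = 1,
                 strand_probability: float = 0.5, seed: int = 0,
                 max_attempts: int = 1000) -> tuple[PromoterSet, PlantLog]:
    """Write motif sites into a copy of the promoter set; log every placement.

    Each selected promoter receives its sites at non-overlapping
    uniform-random offsets; site sequences are sampled column-wise from the
    matrix's smoothed column distributions, reverse-complemented for
    minus-strand placements.  Placement that cannot find room within
    ``max_attempts`` tries raises.
    """
    L = len(pwm)
    if any(len(s) < L for s in promoters.sequences):
        raise ValueError("motif longer than a promoter")
    rng = np.random.default_rng(seed)
    # raw normalized counts (no pseudocount): a consensus-only matrix plants
    # its consensus exactly
    probs = pwm.counts / pwm.counts.sum(axis=1, keepdims=True)
    log = PlantLog()
    new_seqs: list[str] = []
    for pid, seq in promoters:
        if rng.random() >= plant_probability:
            new_seqs.append(seq)
            continue
        n_sites = _draw_site_count(rng, sites_per_promoter)
        placed: list[int] = []
        arr = bytearray(seq, "ascii")
        for _ in range(n_sites):
            for attempt in range(max_attempts):
                off = int(rng.integers(0, len(seq) - L + 1))
                if all(off + L <= o or off >= o + L for o in placed):
                    break
            else:
                raise RuntimeError(f"cannot place {n_sites} non-overlapping sites "
                                   f"of length {L} in {pid}")
            site = "".join(BASES[rng.choice(4, p=probs[i])] for i in range(L))
            strand = "+" if rng.random() < strand_probability else "-"
            written = site if strand == "+" else revcomp(site)
            arr[off:off + L] = written.encode("ascii")
            placed.append(off)
            log.records.append(PlantRecord(pid, pwm.matrix_id, off, strand))
        new_seqs.append(arr.decode("ascii"))
    out = PromoterSet(ids=list(promoters.ids), sequences=new_seqs,
                      upstream=promoters.upstream, downstream=promoters.downstream)
    return out, log


def random_pwm(matrix_id: str, length: int, seed: int = 0, total_count: float = 20.0,
               concentration: float = 0.35) -> PWM:
    """A random informative PWM (peaked Dirichlet columns), for null matrices."""
    rng = np.random.default_rng(seed)
    cols = rng.dirichlet(np.full(4, concentration), size=length)
    return PWM(matrix_id=matrix_id, counts=cols * total_count)


def simulate_enrichment_study(config: SimConfig, pwm: PWM,
                              reference_plant_probability: float = 0.0,
                              ) -> tuple[PromoterSet, PromoterSet, PlantLog, PlantLog]:
    """Target and reference promoter sets with the motif planted at set rates."""
    s1, s2, s3, s4 = spawn_seeds(config.seed, 4)
    targets = gen_background_promoters(config.n_target_promoters, config.promoter_length,
                                       config.background_composition, s1, prefix="target")
    refs = gen_background_promoters(config.n_reference_promoters, config.promoter_length,
                                    config.background_composition, s2, prefix="ref")
    targets, tlog = plant_motifs(targets, pwm, config.plant_probability,
                                 config.sites_per_promoter, config.strand_probability, s3)
    rlog = PlantLog()
    if reference_plant_probability > 0:
        refs, rlog = plant_motifs(refs, pwm, reference_plant_probability,
                                  config.sites_per_promoter, config.strand_probability, s4)
    return targets, refs, tlog, rlog


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionModule:
    """A block of co-regulated genes with per-condition log2 effects."""

    genes: tuple
    effects: Mapping[str, float]


def gen_expression_matrix(n_genes: int, sample_conditions: Sequence[str],
                          modules: Sequence[ExpressionModule] = (),
                          noise_sd: float = 0.3, seed: int = 0,
                          baseline: float = 8.0) -> pd.DataFrame:
    """log2 expression matrix: baseline + block condition effects + Gaussian noise.

    Genes are named ``g0000``...; module ``genes`` may be names or integer
    indices.  Gene blocks must be disjoint.  Genes within a block share their
    condition effects and are therefore positively correlated across samples.
    """
    conditions = list(sample_conditions)
    genes = [f"g{i:04d}" for i in range(n_genes)]
    name_of = {i: g for i, g in enumerate(genes)}

    def _resolve(g):
        return name_of[g] if isinstance(g, (int, np.integer)) else g

    seen: set[str] = set()
    resolved: list[tuple[list[str], Mapping[str, float]]] = []
    for mod in modules:
        block = [_resolve(g) for g in mod.genes]
        overlap = seen.intersection(block)
        if overlap:
            raise ValueError(f"overlapping module gene blocks: {sorted(overlap)[:5]}")
        seen.update(block)
        resolved.append((block, mod.effects))
    rng = np.random.default_rng(seed)
    x = np.full((n_genes, len(conditions)), baseline, dtype=float)
    gene_row = {g: i for i, g in enumerate(genes)}
    for block, effects in resolved:
        rows = [gene_row[g] for g in block]
        shift = np.array([effects.get(cond, 0.0) for cond in conditions])
        x[np.ix_(rows, range(len(conditions)))] += shift
    if noise_sd > 0:
        x += rng.normal(0.0, noise_sd, size=x.shape)
    cols = [f"s{j:02d}_{c}" for j, c in enumerate(conditions)]
    df = pd.DataFrame(x, index=genes, columns=cols)
    df.attrs["conditions"] = conditions
    return df


# ---------------------------------------------------------------------------
# Ortholog promoter alignments with scripted motif gain/loss
# ---------------------------------------------------------------------------

def gen_ortholog_promoters(species: Sequence[str], pwms: Sequence[PWM],
                           presence: Mapping[str, Sequence[str]], seed: int = 0,
                           scaffold_length: int = 1000,
                           substitution_rate: float | Mapping[str, float] = 0.05,
                           deletion_rate: float = 0.01,
                           check_thresholds: Mapping[str, float] | None = None,
                           max_attempts: int = 50,
                           ) -> tuple[AlignmentBlock, pd.DataFrame, dict[str, tuple[int, int]]]:
    """Aligned ortholog promoters sharing a scaffold, motifs present per script.

    Every species' row derives from one ancestral scaffold by per-base
    substitution (and sparse single-base deletions, rendered as gaps at the
    scaffold coordinate, so the returned alignment is exact by construction).
    Each motif occupies one shared scaffold slot; species listed in
    ``presence[matrix_id]`` carry the motif consensus there, others carry
    mutable background sequence.  When ``check_thresholds`` is given the
    realized sequences are scanned and regenerated until the detected
    presence pattern equals the script (bounded attempts), so the returned
    truth table is guaranteed to hold at those thresholds.
    """
    species = list(species)
    unknown = {sp for sps in presence.values() for sp in sps} - set(species)
    if unknown:
        raise ValueError(f"presence script names unknown species: {sorted(unknown)}")
    if set(presence) - {p.matrix_id for p in pwms}:
        raise ValueError("presence script names unknown matrices")
    sub_rate = (substitution_rate if isinstance(substitution_rate, Mapping)
                else {sp: float(substitution_rate) for sp in species})
    for attempt, child in enumerate(spawn_seeds(seed, max_attempts)):
        rng = np.random.default_rng(child)
        scaffold = rng.integers(0, 4, size=scaffold_length).astype(np.int8)
        slots = _assign_slots(rng, [p for p in pwms], scaffold_length)
        rows: list[str] = []
        for sp in species:
            arr = scaffold.copy()
            mut = rng.random(scaffold_length) < sub_rate[sp]
            arr[mut] = (arr[mut] + rng.integers(1, 4, size=int(mut.sum()))) % 4
            dele = rng.random(scaffold_length) < deletion_rate
            for pwm in pwms:
                lo, hi = slots[pwm.matrix_id]
                if sp in presence.get(pwm.matrix_id, ()):
                    arr[lo:hi] = encode(pwm.consensus())
                    dele[lo:hi] = False
            chars = np.array(list(decode(arr)))
            chars[dele] = "-"
            rows.append("".join(chars))
        block = AlignmentBlock(species=species, rows=rows)
        truth = pd.DataFrame(
            {p.matrix_id: [sp in presence.get(p.matrix_id, ()) for sp in species]
             for p in pwms}, index=species)
        if check_thresholds is None:
            return block, truth, slots
        if _presence_matches(block, pwms, check_thresholds, truth):
            return block, truth, slots
    raise RuntimeError(f"could not realize the scripted presence pattern "
                       f"in {max_attempts} attempts")


def _assign_slots(rng: np.random.Generator, pwms: Sequence[PWM],
                  scaffold_length: int, spacing: int = 25,
                  max_attempts: int = 1000) -> dict[str, tuple[int, int]]:
    slots: dict[str, tuple[int, int]] = {}
    taken: list[tuple[int, int]] = []
    for pwm in sorted(pwms, key=lambda p: p.matrix_id):
        L = len(pwm)
        if L > scaffold_length:
            raise ValueError(f"{pwm.matrix_id}: motif longer than scaffold")
        for _ in range(max_attempts):
            lo = int(rng.integers(0, scaffold_length - L + 1))
            if all(lo + L + spacing <= s or lo >= e + spacing for s, e in taken):
                break
        else:
            raise RuntimeError("cannot place non-overlapping motif slots")
        taken.append((lo, lo + L))
        slots[pwm.matrix_id] = (lo, lo + L)
    return slots


def _presence_matches(block: AlignmentBlock, pwms: Sequence[PWM],
                      thresholds: Mapping[str, float], truth: pd.DataFrame) -> bool:
    for pwm in pwms:
        for sp in block.species:
            found = bool(scan(block.ungapped(sp), pwm, thresholds[pwm.matrix_id]))
            if found != bool(truth.loc[sp, pwm.matrix_id]):
                return False
    return True


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------

def gen_ct_table(genes: Sequence[str], groups: Sequence[str],
                 true_fold_changes: Mapping[str, Mapping[str, float]],
                 ct_noise_sd: float = 0.2, n_replicates: int = 6, seed: int = 0,
                 references: Sequence[str] = (), base_ct: float = 22.0) -> pd.DataFrame:
    """Synthetic Ct table: ``Ct = base - log2(relative expression) + noise``.

    ``true_fold_changes[gene][group]`` is the planted relative expression of
    the gene in that group (reference genes must be 1 everywhere).  Each
    (group, replicate) pair is one biological sample carrying one measurement
    of every gene; replicates are independent.
    """
    for ref in references:
        for grp in groups:
            if true_fold_changes.get(ref, {}).get(grp, 1.0) != 1.0:
                raise ValueError(f"reference gene {ref} must have fold change 1 "
                                 f"(group {grp})")
    rng = np.random.default_rng(seed)
    rows = []
    for grp in groups:
        for rep in range(n_replicates):
            sample = f"{grp}_r{rep + 1}"
            for gene in genes:
                fc = true_fold_changes.get(gene, {}).get(grp, 1.0)
                if fc <= 0:
                    raise ValueError(f"fold change must be positive ({gene}, {grp})")
                noise = rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0
                rows.append({"gene": gene, "sample": sample, "group": grp,
                             "replicate": rep + 1,
                             "ct": base_ct - np.log2(fc) + noise})
    return pd.DataFrame(rows, columns=["gene", "sample", "group", "replicate", "ct"])
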