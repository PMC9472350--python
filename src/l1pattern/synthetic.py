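"""Synthetic data: an element family with conserved ORF blocks, aligned
query sets, genomes with planted copies, and insertion/deletion
perturbation experiments.

The generator emulates the structure of a LINE-1-like interspersed
element: a ~6 kb consensus tiled into 5'UTR / ORF1 / inter-ORF / ORF2 /
3'UTR, with sixteen conserved blocks (five in ORF1, eleven in ORF2) whose
columns are guaranteed to stay >= 95% identical across generated members,
plus a poly(A) tail appended to genomic copies.  Everything is
deterministic under an explicit seed.

Member variation is substitutions plus small deletions (rendered as gap
columns, so the returned alignment needs no realignment); divergence
outside the conserved blocks is deliberately high (default 15% per base)
so that a 95% column-conservation threshold cleanly separates designed
blocks from background columns at realistic member counts.  Planted copies
use the same per-member edit process; integrity classes cover intact
copies, 5'-truncated copies, copies with an internal deletion between two
consecutive probe loci (default 396 bases), and heavily decayed copies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ._util import DNA
from .evaluation import Interval
from .probe_design import AlignedQuerySet

__all__ = [
    "ElementModel",
    "PlantedTruth",
    "make_element_model",
    "make_query_set",
    "plant_elements",
    "perturb_genome",
    "random_background",
    "truth_to_intervals",
    "truth_to_gff3",
]

_GAP = ord("-")

# consensus layout fractions for a length-6000 element
_REGIONS_6K = {
    "five_utr": (0, 908),
    "orf1": (908, 1925),
    "inter_orf": (1925, 1988),
    "orf2": (1988, 5816),
    "three_utr": (5816, 6000),
}
_ORF1_BLOCK_STARTS_6K = [930, 1120, 1310, 1500, 1690]
# the gap before the penultimate ORF2 block is widened so that an internal
# deletion of ~400 bases fits between two consecutive probe loci
_ORF2_BLOCK_STARTS_6K = [2020, 2300, 2580, 2860, 3140, 3420, 3700, 3980, 4260, 4900, 5200]
_BLOCK_LEN = 70


@dataclass(frozen=True)
class ElementModel:
    """Consensus sequence plus the generative parameters of the family.

    ``conserved_blocks`` are (region, span) pairs guaranteed >= 95% column
    identity across generated members; ``mutation_rate`` applies per base
    outside blocks, ``block_max_divergence`` caps the fraction of members
    that may deviate in any single block column, and
    ``block_column_mut_prob`` is the chance a block column carries any
    deviation at all.
    """

    consensus: str
    regions: dict[str, tuple[int, int]]
    conserved_blocks: tuple[tuple[str, tuple[int, int]], ...]
    mutation_rate: float = 0.15
    block_max_divergence: float = 0.05
    block_column_mut_prob: float = 0.3
    deletion_events_mean: float = 8.0
    deletion_max_len: int = 3
    polya_range: tuple[int, int] = (12, 28)
    internal_deletion_size: int = 396

    def __post_init__(self):
        length = len(self.consensus)
        covered = sorted(self.regions.values())
        if covered[0][0] != 0 or covered[-1][1] != length:
            raise ValueError("regions must tile the consensus")
        for (_, b0), (a1, _) in zip(covered, covered[1:]):
            if a1 != b0:
                raise ValueError("regions must tile the consensus without gaps")
        for region, (a, b) in self.conserved_blocks:
            ra, rb = self.regions[region.lower()]
            if not (ra <= a < b <= rb):
                raise ValueError("conserved block outside its region")
            if b - a < 50:
                raise ValueError("conserved block shorter than 50 columns")

    @property
    def length(self) -> int:
        return len(self.consensus)

    def block_mask(self) -> np.ndarray:
        mask = np.zeros(self.length, dtype=bool)
        for _, (a, b) in self.conserved_blocks:
            mask[a:b] = True
        return mask

    def internal_deletion_span(self) -> tuple[int, int]:
        """Consensus span of the canonical internal deletion, centered in
        the widened gap between the two consecutive ORF2 blocks."""
        orf2 = [span for region, span in self.conserved_blocks if region == "ORF2"]
        if len(orf2) < 2:
            raise ValueError("model lacks ORF2 blocks")
        gaps = [(b1[0] - a1[1], (a1[1], b1[0])) for a1, b1 in zip(orf2, orf2[1:])]
        widest, (lo, hi) = max(gaps)
        size = self.internal_deletion_size
        if widest < size + 20:
            raise ValueError(
                f"no inter-probe gap can hold an internal deletion of {size} bases"
            )
        start = lo + (widest - size) // 2
        return start, start + size


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth for one planted copy."""

    seqid: str
    start: int
    end: int
    strand: str
    integrity: str
    description: str = ""


def _scale(x: int, length: int) -> int:
    return round(x * length / 6000)


def make_element_model(
    seed: int = 0,
    length: int = 6000,
    mutation_rate: float = 0.15,
    block_max_divergence: float = 0.05,
    block_column_mut_prob: float = 0.3,
    deletion_events_mean: float = 8.0,
) -> ElementModel:
    """Build a deterministic element model; the default layout mirrors a
    full-length LINE-1 (5'UTR, two ORFs separated by a short spacer,
    3'UTR) with 5 + 11 conserved 70-column blocks inside the ORFs."""
    if length < 4000:
        raise ValueError("element length must be >= 4000")
    rng = np.random.default_rng(seed)
    consensus = "".join(rng.choice(list(DNA), size=length))
    regions = {k: (_scale(a, length), _scale(b, length)) for k, (a, b) in _REGIONS_6K.items()}
    blocks: list[tuple[str, tuple[int, int]]] = []
    for s in _ORF1_BLOCK_STARTS_6K:
        a = _scale(s, length)
        blocks.append(("ORF1", (a, a + _BLOCK_LEN)))
    for s in _ORF2_BLOCK_STARTS_6K:
        a = _scale(s, length)
        blocks.append(("ORF2", (a, a + _BLOCK_LEN)))
    return ElementModel(
        consensus=consensus,
        regions=regions,
        conserved_blocks=tuple(blocks),
        mutation_rate=mutation_rate,
        block_max_divergence=block_max_divergence,
        block_column_mut_prob=block_column_mut_prob,
        deletion_events_mean=deletion_events_mean,
    )


def _codes(seq: str) -> np.ndarray:
    lut = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate(DNA):
        lut[ord(b)] = i
    return lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _to_str(codes: np.ndarray, gaps: np.ndarray | None = None) -> str:
    bases = np.frombuffer("ACGT".encode("ascii"), dtype=np.uint8)[codes]
    if gaps is not None:
        bases = bases.copy()
        bases[gaps] = _GAP
    return bases.tobytes().decode("ascii")


def _apply_deletions(
    rng: np.random.Generator, gaps: np.ndarray, allowed: np.ndarray,
    mean_events: float, max_len: int,
) -> None:
    ncol = len(gaps)
    for _ in range(rng.poisson(mean_events)):
        pos = int(rng.integers(0, ncol))
        ln = int(rng.integers(1, max_len + 1))
        span = slice(pos, min(ncol, pos + ln))
        gaps[span] |= allowed[span]


def make_query_set(
    model: ElementModel, n_members: int = 20, seed: int = 0
) -> AlignedQuerySet:
    """Generate an aligned query set of mutated consensus copies.

    Substitutions outside conserved blocks occur at ``model.mutation_rate``
    per base; inside blocks at most ``floor(block_max_divergence *
    n_members)`` members deviate in any column, guaranteeing the blocks
    pass a 95% column-conservation scan.  Small deletions outside blocks
    appear as gap columns.
    """
    if n_members < 2:
        raise ValueError("need at least 2 members")
    rng = np.random.default_rng(seed)
    ncol = model.length
    block = model.block_mask()
    nonblock = ~block
    cons = _codes(model.consensus)

    rows = np.tile(cons, (n_members, 1))
    mut = (rng.random((n_members, ncol)) < model.mutation_rate) & nonblock[None, :]
    shift = rng.integers(1, 4, size=(n_members, ncol), dtype=np.uint8)
    rows[mut] = (rows[mut] + shift[mut]) % 4

    cap = int(model.block_max_divergence * n_members)
    if cap >= 1:
        for col in np.flatnonzero(block):
            if rng.random() >= model.block_column_mut_prob:
                continue
            count = int(rng.integers(1, cap + 1))
            members = rng.choice(n_members, size=count, replace=False)
            rows[members, col] = (rows[members, col] + rng.integers(1, 4, size=count)) % 4

    members = []
    for i in range(n_members):
        gaps = np.zeros(ncol, dtype=bool)
        _apply_deletions(rng, gaps, nonblock, model.deletion_events_mean, model.deletion_max_len)
        members.append((f"Q{i + 1:03d}", _to_str(rows[i], gaps)))

    return AlignedQuerySet(
        members=tuple(members),
        orf_ranges={"ORF1": model.regions["orf1"], "ORF2": model.regions["orf2"]},
        element_span=(0, ncol),
    )


def _make_copy(
    model: ElementModel, rng: np.random.Generator, integrity: str = "intact"
) -> tuple[str, str]:
    """One genomic copy of the element (sequence, description)."""
    ncol = model.length
    block = model.block_mask()
    nonblock = ~block
    row = _codes(model.consensus).copy()

    if integrity == "decayed":
        sub_rate = np.full(ncol, 0.25)
    else:
        sub_rate = np.where(
            block, model.block_column_mut_prob * model.block_max_divergence, model.mutation_rate
        )
    mut = rng.random(ncol) < sub_rate
    row[mut] = (row[mut] + rng.integers(1, 4, size=int(mut.sum()), dtype=np.uint8)) % 4

    gaps = np.zeros(ncol, dtype=bool)
    allowed = np.ones(ncol, dtype=bool) if integrity == "decayed" else nonblock
    _apply_deletions(rng, gaps, allowed, model.deletion_events_mean, model.deletion_max_len)

    desc = integrity
    if integrity == "truncated_5p":
        cut = int(rng.integers(_scale(800, ncol), _scale(4200, ncol)))
        gaps[:cut] = True
        desc = f"truncated_5p:{cut}"
    elif integrity == "internal_deletion":
        lo, hi = model.internal_deletion_span()
        gaps[lo:hi] = True
        desc = f"internal_deletion:{hi - lo}@{lo}"
    elif integrity not in ("intact", "decayed"):
        raise ValueError(f"unknown integrity class {integrity!r}")

    seq = _to_str(row[~gaps])
    polya = "A" * int(rng.integers(model.polya_range[0], model.polya_range[1] + 1))
    return seq + polya, desc


def random_background(length: int, seed: int = 0, chrom: str = "chr1") -> dict[str, str]:
    """Uniform i.i.d. ACGT background sequence."""
    rng = np.random.default_rng(seed)
    return {chrom: _to_str(rng.integers(0, 4, size=length, dtype=np.uint8))}


def _class_sequence(
    n_copies: int, class_mix: dict[str, float], rng: np.random.Generator
) -> list[str]:
    classes = sorted(class_mix)
    counts = {c: int(round(class_mix[c] * n_copies)) for c in classes}
    while sum(counts.values()) > n_copies:
        counts[max(classes, key=lambda c: counts[c])] -= 1
    while sum(counts.values()) < n_copies:
        counts[min(classes, key=lambda c: counts[c])] += 1
    seq = [c for c in classes for _ in range(counts[c])]
    rng.shuffle(seq)
    return seq


def plant_elements(
    background_length: int,
    model: ElementModel,
    n_copies: int,
    class_mix: dict[str, float] | None = None,
    seed: int = 0,
    chrom: str = "chr1",
    min_gap: int = 800,
) -> tuple[dict[str, str], list[PlantedTruth]]:
    """Plant element copies in random background sequence.

    Copies are inserted at non-overlapping positions at least ``min_gap``
    of background apart, each on a random strand.  The returned truth
    records every copy with its final coordinates and integrity class.
    """
    rng = np.random.default_rng(seed)
    background = random_background(background_length, seed=int(rng.integers(2**31)), chrom=chrom)[chrom]
    if n_copies == 0:
        return {chrom: background}, []
    mix = class_mix or {"intact": 1.0}
    classes = _class_sequence(n_copies, mix, rng)
    room = background_length - (n_copies + 1) * min_gap
    if room < 0:
        raise ValueError("background too short for the requested copies")
    offs = np.sort(rng.integers(0, room + 1, size=n_copies))
    positions = [int(offs[i]) + min_gap * (i + 1) for i in range(n_copies)]

    from ._util import revcomp

    pieces: list[str] = []
    truth: list[PlantedTruth] = []
    prev = 0
    placed = 0
    for pos, integrity in zip(positions, classes):
        pieces.append(background[prev:pos])
        placed += pos - prev
        seq, desc = _make_copy(model, rng, integrity)
        strand = "+" if rng.random() < 0.5 else "-"
        ins = seq if strand == "+" else revcomp(seq)
        truth.append(PlantedTruth(chrom, placed, placed + len(ins), strand, integrity, desc))
        pieces.append(ins)
        placed += len(ins)
        prev = pos
    pieces.append(background[prev:])
    return {chrom: "".join(pieces)}, truth


def perturb_genome(
    genome: dict[str, str],
    truth: Sequence[PlantedTruth],
    model: ElementModel,
    n_insert: int = 0,
    n_delete: int = 0,
    seed: int = 0,
    min_gap: int = 800,
) -> tuple[dict[str, str], list[PlantedTruth]]:
    """Delete whole planted copies and/or insert fresh intact ones.

    Deletions excise the full recorded span; insertions go into background
    at least ``min_gap`` away from any existing copy.  The resulting truth
    has ``len(truth) + n_insert - n_delete`` records.
    """
    truth = list(truth)
    if n_delete > len(truth):
        raise ValueError("cannot delete more copies than exist")
    rng = np.random.default_rng(seed)
    genome = dict(genome)

    if n_delete:
        victims = set(rng.choice(len(truth), size=n_delete, replace=False).tolist())
        by_chrom: dict[str, list[PlantedTruth]] = {}
        for i in sorted(victims, key=lambda i: -truth[i].start):
            by_chrom.setdefault(truth[i].seqid, []).append(truth[i])
        survivors = [t for i, t in enumerate(truth) if i not in victims]
        for chrom, victims_list in by_chrom.items():
            seq = genome[chrom]
            for v in victims_list:  # right-to-left
                seq = seq[: v.start] + seq[v.end :]
                survivors = [
                    t
                    if t.seqid != chrom or t.start < v.start
                    else PlantedTruth(t.seqid, t.start - (v.end - v.start), t.end - (v.end - v.start), t.strand, t.integrity, t.description)
                    for t in survivors
                ]
            genome[chrom] = seq
        truth = survivors

    from ._util import revcomp

    for _ in range(n_insert):
        chrom = list(genome)[int(rng.integers(0, len(genome)))]
        seq = genome[chrom]
        occupied = sorted(
            (max(0, t.start - min_gap), min(len(seq), t.end + min_gap))
            for t in truth
            if t.seqid == chrom
        )
        free: list[tuple[int, int]] = []
        cursor = 0
        for a, b in occupied:
            if a > cursor:
                free.append((cursor, a))
            cursor = max(cursor, b)
        if cursor < len(seq):
            free.append((cursor, len(seq)))
        total = sum(b - a for a, b in free)
        if total <= 0:
            raise ValueError("no room left to insert a copy")
        pick = int(rng.integers(0, total))
        for a, b in free:
            if pick < b - a:
                point = a + pick
                break
            pick -= b - a
        new_seq, desc = _make_copy(model, rng, "intact")
        strand = "+" if rng.random() < 0.5 else "-"
        ins = new_seq if strand == "+" else revcomp(new_seq)
        genome[chrom] = seq[:point] + ins + seq[point:]
        shifted = []
        for t in truth:
            if t.seqid == chrom and t.start >= point:
                shifted.append(
                    PlantedTruth(t.seqid, t.start + len(ins), t.end + len(ins), t.strand, t.integrity, t.description)
                )
            else:
                shifted.append(t)
        truth = shifted
        truth.append(PlantedTruth(chrom, point, point + len(ins), strand, "intact", desc))

    truth.sort(key=lambda t: (t.seqid, t.start))
    return genome, truth


def truth_to_intervals(truth: Sequence[PlantedTruth]) -> list[Interval]:
    return [Interval(t.seqid, t.start, t.end, t.strand) for t in truth]


def truth_to_gff3(truth: Sequence[PlantedTruth], path: str | Path) -> None:
    """Write planted truth as GFF3 (source ``synthetic``)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in sorted(truth, key=lambda t: (t.seqid, t.start)):
            attrs = f"Name=LINE1;integrity={t.integrity}"
            if t.description and t.description != t.integrity:
                attrs += f";note={t.description}"
            fh.write(
                f"{t.seqid}\tsynthetic\tmobile_genetic_element\t{t.start + 1}\t{t.end}\t.\t{t.strand}\t.\t{attrs}\n"
            )
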