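"""C2H2 zinc-finger annotation, helix-relative numbering, and
position-probability profile scoring.

A classical C2H2 finger is a ~23-28 residue ββα unit in which two
cysteines (on the beta-hairpin) and two histidines (on the alpha-helix)
coordinate a zinc ion.  The field numbers helix residues relative to
the first residue of the recognition helix: that residue is +1, the one
immediately before it is -1, and there is no position 0.  The first
zinc-binding histidine sits at +7, which anchors the numbering: this
module sets ``helix_start = his1 - 6``.  The canonical DNA-contacting
positions are -1, +1, +2, +3 and +6.

Residue typicality is scored against a position-probability profile
built from an alignment of C2H2 fingers: per-column probabilities with
pseudocounts, column information content (relative entropy to
background, the logo stack height), and per-position log-odds
``log2(p/q)`` whose sum measures how typical a query finger's
DNA-binding residues are relative to the family.  This replaces a full
profile HMM: the inputs are fixed-width finger alignments, so insert
and delete states buy nothing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .errors import DataError
from .shift_io import AMINO_ACIDS, Alignment

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: Canonical DNA-recognition positions relative to the helix.
DNA_BINDING_POSITIONS = (-1, 1, 2, 3, 6)

# C-x(2,4)-C-x(3)-[FYLIVW]-x(5)-[hydrophobic]-x(2)-H-x(3,5)-H
_C2H2_RE = re.compile(
    r"C.{2,4}(C).{3}[FYLIVW].{5}[AVLIMFWYC].{2}(H).{3,5}(H)"
)

# flanking residues kept around the matched C2H2 core: two before the
# first cysteine (the beta-hairpin cap) and four after the second
# histidine (helix tail / start of the TGEKP-style linker)
_LEFT_MARGIN = 2
_RIGHT_MARGIN = 4


@dataclass(frozen=True)
class HelixPosition:
    """Helix-relative position: a nonzero signed integer."""

    value: int

    def __post_init__(self) -> None:
        if self.value == 0:
            raise DataError("helix-relative position 0 does not exist")

    def __int__(self) -> int:
        return self.value

    def __str__(self) -> str:
        return f"+{self.value}" if self.value > 0 else str(self.value)


@dataclass
class ZincFingerAnnotation:
    """One C2H2 finger with absolute residue numbering.

    ``helix_start`` is the residue at helix position +1;
    ``helix_end`` is the second zinc-binding histidine.
    """

    sequence: str
    start: int  # absolute residue number of sequence[0]
    cys1: int
    cys2: int
    his1: int
    his2: int
    helix_start: int
    helix_end: int

    def __post_init__(self) -> None:
        end = self.start + len(self.sequence) - 1
        if not (self.cys1 < self.cys2 < self.his1 < self.his2):
            raise DataError("zinc-coordinating residues out of order")
        if not (self.helix_start <= self.his1 <= self.helix_end):
            raise DataError("his1 must lie within the helix")
        for r in (self.cys1, self.cys2, self.his1, self.his2, self.helix_start, self.helix_end):
            if not (self.start <= r <= end):
                raise DataError(f"residue {r} outside sequence span {self.start}-{end}")

    @property
    def end(self) -> int:
        return self.start + len(self.sequence) - 1

    def residue_type(self, residue_number: int) -> str:
        if not (self.start <= residue_number <= self.end):
            raise DataError(f"residue {residue_number} outside span {self.start}-{self.end}")
        return self.sequence[residue_number - self.start]


def annotate_c2h2(sequence: str, start: int = 1) -> list[ZincFingerAnnotation]:
    """Scan a sequence for classical C2H2 fingers.

    Matches ``C-x(2,4)-C-x(3)-[FYLIVW]-x(5)-[hydrophobic]-x(2)-H-x(3,5)-H``;
    overlapping candidates are resolved leftmost (then longest via
    greedy spacers).  Returns an empty list when nothing matches.
    ``start`` is the absolute residue number of ``sequence[0]``.
    """
    seq = sequence.upper()
    if len(seq) < 12:
        raise DataError("sequence too short to contain a C2H2 finger")
    matches = []
    pos = 0
    while True:
        m = _C2H2_RE.search(seq, pos)
        if m is None:
            break
        matches.append(m)
        pos = m.end()
    out = []
    for i, m in enumerate(matches):
        # include flanking context (fingers extend a little past the
        # C2H2 core: an N-terminal cap and the C-terminal helix tail /
        # linker), clipped so adjacent fingers never overlap
        left = m.start() - _LEFT_MARGIN
        if i > 0:
            left = max(left, matches[i - 1].end())
        left = max(left, 0)
        right = m.end() + _RIGHT_MARGIN
        if i + 1 < len(matches):
            right = min(right, matches[i + 1].start())
        right = min(right, len(seq))
        out.append(
            ZincFingerAnnotation(
                sequence=seq[left:right],
                start=start + left,
                cys1=start + m.start(),
                cys2=start + m.start(1),
                his1=start + m.start(2),
                his2=start + m.start(3),
                helix_start=start + m.start(2) - 6,
                helix_end=start + m.start(3),
            )
        )
    return out


def helix_position(residue_number: int, annotation: ZincFingerAnnotation) -> HelixPosition:
    """Helix-relative label of a residue: +1 is the first helix residue,
    -1 the residue immediately before it; 0 is never produced."""
    if not (annotation.start <= residue_number <= annotation.end):
        raise DataError(
            f"residue {residue_number} outside annotation span "
            f"{annotation.start}-{annotation.end}"
        )
    if residue_number >= annotation.helix_start:
        return HelixPosition(residue_number - annotation.helix_start + 1)
    return HelixPosition(residue_number - annotation.helix_start)


def residue_at_position(annotation: ZincFingerAnnotation, position: HelixPosition | int) -> int:
    """Inverse of :func:`helix_position`."""
    value = int(position)
    if value == 0:
        raise DataError("helix-relative position 0 does not exist")
    if value > 0:
        resnum = annotation.helix_start + value - 1
    else:
        resnum = annotation.helix_start + value
    if not (annotation.start <= resnum <= annotation.end):
        raise DataError(f"position {value} falls outside the annotation span")
    return resnum


def dna_binding_residues(annotation: ZincFingerAnnotation) -> dict[int, tuple[int, str]]:
    """The five canonical DNA-recognition positions and their residues."""
    out = {}
    for pos in DNA_BINDING_POSITIONS:
        resnum = residue_at_position(annotation, pos)
        out[pos] = (resnum, annotation.residue_type(resnum))
    return out


# ---------------------------------------------------------------------------
# position-probability profiles


@dataclass
class PositionProfile:
    """Per-column amino-acid probabilities with pseudocounts."""

    columns: np.ndarray  # (width, 20)
    background: np.ndarray  # (20,)
    pseudocount: float
    all_gap_columns: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.columns = np.asarray(self.columns, float)
        self.background = np.asarray(self.background, float)
        if self.columns.ndim != 2 or self.columns.shape[1] != 20:
            raise DataError("profile columns must be (width, 20)")
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise DataError("background must sum to 1")
        sums = self.columns.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise DataError("every profile column must sum to 1")

    @property
    def width(self) -> int:
        return self.columns.shape[0]

    def probability(self, column: int, aa: str) -> float:
        return float(self.columns[column, _AA_INDEX[aa]])


def build_profile(
    alignment: Alignment,
    pseudocount: float = 1.0,
    background: np.ndarray | str = "uniform",
) -> PositionProfile:
    """Column probabilities ``(n_c(a) + lam*q(a)) / (N_c + lam)``.

    Gaps (and X) are excluded from the column count ``N_c``.  An
    all-gap column is flagged and assigned the background.
    """
    if background == "uniform" or background is None:
        q = np.full(20, 1 / 20)
    else:
        q = np.asarray(background, float)
        if q.shape != (20,) or abs(q.sum() - 1.0) > 1e-9:
            raise DataError("background must be 20 probabilities summing to 1")
    lam = float(pseudocount)
    if lam < 0:
        raise DataError("pseudocount must be >= 0")
    width = alignment.width
    cols = np.zeros((width, 20))
    all_gap = []
    for c in range(width):
        counts = np.zeros(20)
        for seq in alignment.seqs:
            aa = seq[c]
            if aa in _AA_INDEX:
                counts[_AA_INDEX[aa]] += 1
        n_c = counts.sum()
        if n_c == 0:
            cols[c] = q
            all_gap.append(c)
        else:
            cols[c] = (counts + lam * q) / (n_c + lam)
    return PositionProfile(cols, q, lam, all_gap)


def information_content(profile: PositionProfile) -> np.ndarray:
    """Per-column relative entropy to background, in bits."""
    p = profile.columns
    q = profile.background
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p / q), 0.0)
    return terms.sum(axis=1)


@dataclass
class AtypicalityScore:
    """Log-odds typicality of a query finger's DNA-binding residues."""

    per_position: dict[int, float]  # helix position -> log2(p/q)
    total: float
    percentile: float | None  # of the total among profile-sampled sequences
    n_samples: int


def atypicality_score(
    query: ZincFingerAnnotation,
    profile: PositionProfile,
    column_map: dict[int, int],
    n_samples: int = 2000,
    seed: int = 0,
) -> AtypicalityScore:
    """Score how (a)typical the query's DNA-binding residues are.

    ``column_map`` maps each of the five helix positions to a profile
    column.  Per position the score is ``log2(p_col(a)/q(a))`` for the
    query residue ``a``; the total is their sum.  A low (negative)
    total marks an atypical DNA-binding residue pattern.  The total is
    also placed among ``n_samples`` profile-sampled position sets as a
    mid-rank percentile (seeded), so 0.5 means "as typical as the
    family average draw".
    """
    missing = [p for p in DNA_BINDING_POSITIONS if p not in column_map]
    if missing:
        raise DataError(f"column_map lacks helix position {missing[0]}")
    per_pos = {}
    for pos in DNA_BINDING_POSITIONS:
        col = column_map[pos]
        if not 0 <= col < profile.width:
            raise DataError(f"column {col} outside profile width {profile.width}")
        resnum = residue_at_position(query, pos)
        aa = query.residue_type(resnum)
        if aa not in _AA_INDEX:
            raise DataError(f"query residue {resnum} has non-standard type {aa!r}")
        p = profile.probability(col, aa)
        q = float(profile.background[_AA_INDEX[aa]])
        per_pos[pos] = float(np.log2(p / q))
    total = float(sum(per_pos.values()))

    percentile = None
    if n_samples > 0:
        rng = np.random.default_rng(seed)
        logodds = np.log2(profile.columns / profile.background)
        sampled = np.zeros(n_samples)
        for pos in DNA_BINDING_POSITIONS:
            col = column_map[pos]
            idx = rng.choice(20, size=n_samples, p=profile.columns[col])
            sampled += logodds[col, idx]
        less = float(np.count_nonzero(sampled < total))
        equal = float(np.count_nonzero(sampled == total))
        percentile = (less + 0.5 * equal) / n_samples
    return AtypicalityScore(per_pos, total, percentile, n_samples)
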