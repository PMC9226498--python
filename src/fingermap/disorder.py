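"""Chemical-shift-based order/disorder estimation.

Secondary chemical shifts (observed minus residue-type random-coil
reference) report on backbone structure: a segment whose CA, CB, C'
and proton shifts all sit at their random-coil values is disordered,
while systematic deviations mark secondary structure.  A random-coil
index condenses this per residue:

    A_i   = weighted mean of |secondary shift| over available atoms
    RCI_i = 1 / max(A_i, floor)          (after window smoothing of A)
    S2_i  = clamp(1 - c * RCI_i, 0, 1)

so larger secondary shifts give a larger order parameter S2 in [0, 1];
residues at the random-coil baseline land at S2 = 0.  The default
constants (floor 0.05 ppm, c 0.05, proton weights 5x, nitrogen 0.2x,
window 3) put an ideal helix near S2 ~ 0.9 and pure coil with typical
noise well below the 0.7 region cutoff; they are readouts of the
structured/disordered contrast, not quantitative relaxation-grade S2
values.  Atoms missing from the reference (glycine CB, proline amide
proton) are omitted, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError
from .reference_shifts import random_coil_table
from .shift_io import ShiftTable

#: Per-atom weights used in the weighted mean |secondary shift|;
#: protons are up-weighted to put their smaller ppm range on a
#: carbon-comparable scale, nitrogen (broad intrinsic dispersion) down.
DEFAULT_WEIGHTS = {"CA": 1.0, "CB": 1.0, "C": 1.0, "H": 5.0, "HA": 5.0, "N": 0.2}

DEFAULT_FLOOR = 0.05  # ppm: A_i at or below this is "fully coil"
DEFAULT_C = 0.05      # S2 = 1 - c * RCI
DEFAULT_WINDOW = 3
DEFAULT_S2_CUTOFF = 0.7
MIN_RUN = 3


def secondary_shifts(
    table: ShiftTable,
    reference: dict[str, dict[str, float]] | None = None,
) -> dict[int, dict[str, float]]:
    """Observed minus random-coil reference, per residue and atom.

    Atoms absent from the reference for that residue type (e.g. CB of
    glycine) are omitted.  A residue type missing from the reference
    entirely is an error naming the residue.
    """
    ref = reference or random_coil_table()
    out: dict[int, dict[str, float]] = {}
    for resnum, atoms in table.by_residue().items():
        aa = table.residue_type(resnum)
        if aa not in ref:
            raise DataError(f"residue {resnum} has type {aa!r} absent from the random-coil reference")
        ref_atoms = ref[aa]
        deltas = {
            atom: obs - ref_atoms[atom]
            for atom, obs in atoms.items()
            if atom in ref_atoms
        }
        if deltas:
            out[resnum] = deltas
    return out


@dataclass
class DisorderProfile:
    """Per-residue disorder readout from chemical shifts."""

    residues: list[int]
    mean_abs_secondary: dict[int, float]  # smoothed A_i, ppm
    rci: dict[int, float]
    s2: dict[int, float]
    window: int
    flagged: list[int] = field(default_factory=list)  # too few atoms

    def __post_init__(self) -> None:
        for r, v in self.s2.items():
            if not 0.0 <= v <= 1.0:
                raise DataError(f"s2 out of [0,1] for residue {r}")
        for r, v in self.rci.items():
            if not v > 0:
                raise DataError(f"non-positive rci for residue {r}")


def rci_s2(
    table: ShiftTable,
    weights: dict[str, float] | None = None,
    window: int = DEFAULT_WINDOW,
    floor: float = DEFAULT_FLOOR,
    c: float = DEFAULT_C,
    min_atoms: int = 2,
) -> DisorderProfile:
    """Random-coil index and S2 estimate per residue.

    ``window`` (odd) is the centred moving-average width applied to the
    raw A_i profile; smoothing runs over consecutive residue numbers
    only.  Residues with fewer than ``min_atoms`` referenced atoms are
    flagged and excluded rather than fabricated.
    """
    if window < 1 or window % 2 == 0:
        raise DataError("window must be a positive odd integer")
    w = weights or DEFAULT_WEIGHTS
    deltas = secondary_shifts(table)
    raw: dict[int, float] = {}
    flagged: list[int] = []
    for resnum, atom_deltas in sorted(deltas.items()):
        usable = {a: d for a, d in atom_deltas.items() if a in w}
        if len(usable) < min_atoms:
            flagged.append(resnum)
            continue
        wsum = sum(w[a] for a in usable)
        raw[resnum] = sum(w[a] * abs(d) for a, d in usable.items()) / wsum
    if len(raw) < window:
        raise DataError("too few residues with enough atoms for the requested window")

    residues = sorted(raw)
    half = window // 2
    smoothed: dict[int, float] = {}
    for r in residues:
        vals = [raw[r + k] for k in range(-half, half + 1) if (r + k) in raw]
        smoothed[r] = float(np.mean(vals))

    rci = {r: 1.0 / max(a, floor) for r, a in smoothed.items()}
    s2 = {r: float(np.clip(1.0 - c * v, 0.0, 1.0)) for r, v in rci.items()}
    return DisorderProfile(residues, smoothed, rci, s2, window, flagged)


def classify_regions(
    profile: DisorderProfile,
    s2_cutoff: float = DEFAULT_S2_CUTOFF,
    min_run: int = MIN_RUN,
) -> list[tuple[int, int, str]]:
    """Maximal ordered/disordered runs of the S2 profile.

    Residues with S2 > cutoff are "ordered", the rest "disordered".
    Runs shorter than ``min_run`` are merged into the preceding run
    (or the following one at the profile start).  Numbering gaps split
    regions unconditionally.
    """
    residues = profile.residues
    if not residues:
        return []
    segments: list[list[int]] = [[residues[0]]]
    for prev, cur in zip(residues, residues[1:]):
        if cur == prev + 1:
            segments[-1].append(cur)
        else:
            segments.append([cur])

    out: list[tuple[int, int, str]] = []
    for seg in segments:
        labels = ["ordered" if profile.s2[r] > s2_cutoff else "disordered" for r in seg]
        runs: list[list[int, int, str]] = []  # [start_idx, end_idx, label]
        for i, lab in enumerate(labels):
            if runs and runs[-1][2] == lab:
                runs[-1][1] = i
            else:
                runs.append([i, i, lab])
        # merge short runs into their neighbours until stable
        changed = True
        while changed and len(runs) > 1:
            changed = False
            for i, run in enumerate(runs):
                if run[1] - run[0] + 1 < min_run:
                    target = i - 1 if i > 0 else i + 1
                    runs[target][0] = min(runs[target][0], run[0])
                    runs[target][1] = max(runs[target][1], run[1])
                    del runs[i]
                    # re-merge adjacent runs that now share a label
                    j = 1
                    while j < len(runs):
                        if runs[j][2] == runs[j - 1][2]:
                            runs[j - 1][1] = runs[j][1]
                            del runs[j]
                        else:
                            j += 1
                    changed = True
                    break
        for run in runs:
            out.append((seg[run[0]], seg[run[1]], run[2]))
    return out
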