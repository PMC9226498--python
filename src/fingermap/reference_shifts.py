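"""Random-coil chemical-shift references and helix secondary offsets.

The per-residue random-coil values (ppm) shipped in
``data/random_coil_shifts.tsv`` follow the widely used compilations of
Wishart and co-workers for the backbone nuclei CA, CB, C', HN, N and
HA.  Neighbour-residue (sequence) corrections are deliberately not
applied; for the order/disorder contrast this pipeline draws, the
uncorrected references are sufficient and keep the reference a plain
lookup.  Glycine has no CB and proline no amide proton; those entries
are simply absent and downstream code omits the atom rather than
imputing a value.
"""

from __future__ import annotations

import csv
from functools import lru_cache
from importlib import resources

#: Canonical helix secondary-shift offsets in ppm at amplitude 1
#: (observed minus random coil for an ideal alpha-helix): 13CA moves
#: downfield, 13CB and the protons upfield.
HELIX_SECONDARY: dict[str, float] = {
    "CA": 2.6,
    "CB": -0.5,
    "C": 1.8,
    "H": -0.25,
    "N": -1.5,
    "HA": -0.35,
}


@lru_cache(maxsize=1)
def random_coil_table() -> dict[str, dict[str, float]]:
    """Load the random-coil reference: aa -> atom -> shift (ppm)."""
    table: dict[str, dict[str, float]] = {}
    source = resources.files("fingermap").joinpath("data/random_coil_shifts.tsv")
    with source.open("rt", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            aa = row.pop("aa")
            table[aa] = {
                atom: float(v) for atom, v in row.items() if v not in ("", "NA")
            }
    return table
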