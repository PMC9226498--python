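"""Readers and writers for on-disk NMR artifacts.

Canonical interchange is a small TSV dialect:

* shift table:       ``residue  aa  atom  shift_ppm``
* amide peak list:   ``residue  h_ppm  n_ppm``
* titration manifest ``p_total_M  l_total_M  peaklist_path``

plus read-only support for the ``Atom_chem_shift`` loop of NMR-STAR v3
(the subset needed to load BMRB chemical-shift depositions), aligned
FASTA for zinc-finger alignments, and fixed-column PDB for structures.

Residue numbering is 1-based throughout and follows the coordinates of
the protein construct under study (e.g. a fragment spanning residues
87-153 keeps those numbers).  Prolines and unassigned residues are
simply absent from peak lists; missing peaks at individual titration
points are allowed, since peak overlap routinely defeats tracking.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TextIO

from Bio import AlignIO

from .errors import DataError

#: Backbone atoms the pipeline understands.  Anything else in an input
#: table is skipped and counted in the parse report.
SUPPORTED_ATOMS = frozenset({"H", "N", "CA", "CB", "C", "HA"})

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class ShiftRecord:
    """One backbone chemical shift: residue, atom, shift in ppm."""

    residue_number: int
    residue_type: str
    atom: str
    shift: float

    def __post_init__(self) -> None:
        if self.residue_number < 1:
            raise DataError(f"residue_number must be >= 1, got {self.residue_number}")
        if self.atom not in SUPPORTED_ATOMS:
            raise DataError(f"unsupported atom {self.atom!r}")
        if not _finite(self.shift):
            raise DataError(f"non-finite shift for residue {self.residue_number}")


@dataclass
class ParseReport:
    """Bookkeeping from a reader: rows kept, rows skipped and why."""

    n_parsed: int = 0
    n_skipped: int = 0
    skipped: list[str] = field(default_factory=list)


@dataclass
class ShiftTable:
    """Per-residue backbone chemical shifts for one sample state."""

    records: list[ShiftRecord]
    sample_label: str = ""
    report: ParseReport | None = None

    def __post_init__(self) -> None:
        seen: set[tuple[int, str]] = set()
        for rec in self.records:
            key = (rec.residue_number, rec.atom)
            if key in seen:
                raise DataError(f"duplicate (residue, atom) entry {key}")
            seen.add(key)

    def get(self, residue_number: int, atom: str) -> float | None:
        for rec in self.records:
            if rec.residue_number == residue_number and rec.atom == atom:
                return rec.shift
        return None

    def residues(self) -> list[int]:
        return sorted({r.residue_number for r in self.records})

    def residue_type(self, residue_number: int) -> str | None:
        for rec in self.records:
            if rec.residue_number == residue_number:
                return rec.residue_type
        return None

    def by_residue(self) -> dict[int, dict[str, float]]:
        out: dict[int, dict[str, float]] = {}
        for rec in self.records:
            out.setdefault(rec.residue_number, {})[rec.atom] = rec.shift
        return out

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class AmidePeak:
    """One amide cross-peak: residue and its 1H / 15N positions in ppm."""

    residue_number: int
    h_ppm: float
    n_ppm: float

    def __post_init__(self) -> None:
        if self.residue_number < 1:
            raise DataError(f"residue_number must be >= 1, got {self.residue_number}")
        if not (_finite(self.h_ppm) and _finite(self.n_ppm)):
            raise DataError(f"non-finite peak for residue {self.residue_number}")


@dataclass
class TitrationPoint:
    """One titration point: total concentrations (mol/L) plus its peak list."""

    p_total: float
    l_total: float
    peaks: list[AmidePeak]

    def __post_init__(self) -> None:
        if not self.p_total > 0:
            raise DataError("p_total must be > 0")
        if self.l_total < 0:
            raise DataError("l_total must be >= 0")
        seen: set[int] = set()
        for pk in self.peaks:
            if pk.residue_number in seen:
                raise DataError(f"duplicate peak for residue {pk.residue_number}")
            seen.add(pk.residue_number)

    @property
    def ratio(self) -> float:
        return self.l_total / self.p_total

    def peak_map(self) -> dict[int, AmidePeak]:
        return {pk.residue_number: pk for pk in self.peaks}


@dataclass
class TitrationSeries:
    """Ordered titration points sharing one binding event.

    The first point is the apo reference (``l_total == 0``); points are
    kept sorted by ligand:protein ratio, and every residue observed at
    a later point must also be present in the apo point.
    """

    points: list[TitrationPoint]

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise DataError("a titration series needs at least 2 points")
        self.points = sorted(self.points, key=lambda p: p.ratio)
        if self.points[0].l_total != 0:
            raise DataError("titration series must contain an apo point (l_total = 0)")
        apo = set(self.points[0].peak_map())
        for pt in self.points[1:]:
            extra = set(pt.peak_map()) - apo
            if extra:
                raise DataError(
                    f"residue {sorted(extra)[0]} appears at ratio {pt.ratio:g} "
                    "but not in the apo point"
                )

    @property
    def apo(self) -> TitrationPoint:
        return self.points[0]

    def residues(self) -> list[int]:
        return sorted(self.apo.peak_map())

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class Alignment:
    """Equal-length gapped amino-acid sequences with identifiers."""

    ids: list[str]
    seqs: list[str]

    def __post_init__(self) -> None:
        if not self.seqs:
            raise DataError("empty alignment")
        width = len(self.seqs[0])
        for ident, seq in zip(self.ids, self.seqs):
            if len(seq) != width:
                raise DataError(f"ragged alignment: sequence {ident!r} has length {len(seq)}, expected {width}")

    @property
    def width(self) -> int:
        return len(self.seqs[0])

    def __len__(self) -> int:
        return len(self.seqs)

    def column(self, i: int) -> str:
        return "".join(seq[i] for seq in self.seqs)


def _finite(x: float) -> bool:
    return x == x and x not in (float("inf"), float("-inf"))


# ---------------------------------------------------------------------------
# shift tables


def read_shift_table(source: TextIO | str, dialect: str = "tsv", sample_label: str = "") -> ShiftTable:
    """Parse a chemical-shift table from a text stream or path.

    ``dialect`` is ``"tsv"`` (native) or ``"nmrstar_subset"`` (the
    ``Atom_chem_shift`` loop columns Comp_index_ID / Comp_ID / Atom_ID /
    Val of an NMR-STAR v3 file, enough to load BMRB depositions).
    Rows whose atom is outside :data:`SUPPORTED_ATOMS` are skipped and
    counted in the returned table's ``report``.
    """
    stream = _as_stream(source)
    if dialect == "tsv":
        return _read_shift_tsv(stream, sample_label)
    if dialect == "nmrstar_subset":
        return _read_shift_star(stream, sample_label)
    raise DataError(f"unknown dialect {dialect!r}")


def _read_shift_tsv(stream: TextIO, sample_label: str) -> ShiftTable:
    report = ParseReport()
    records: list[ShiftRecord] = []
    header = stream.readline()
    if not header:
        raise DataError("no records: empty shift table")
    cols = header.rstrip("\n").split("\t")
    if cols != ["residue", "aa", "atom", "shift_ppm"]:
        raise DataError(f"bad shift-table header: {header.strip()!r}")
    for lineno, line in enumerate(stream, start=2):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 4:
            raise DataError(f"malformed shift-table row at line {lineno}")
        try:
            resnum = int(parts[0])
            aa = parts[1].strip().upper()
            atom = parts[2].strip().upper()
            shift = float(parts[3])
        except ValueError as exc:
            raise DataError(f"malformed shift-table row at line {lineno}: {exc}") from None
        if atom not in SUPPORTED_ATOMS:
            report.n_skipped += 1
            report.skipped.append(f"line {lineno}: unsupported atom {atom}")
            continue
        records.append(ShiftRecord(resnum, aa, atom, shift))
        report.n_parsed += 1
    if not records and report.n_skipped == 0:
        raise DataError("no records in shift table")
    table = ShiftTable(records, sample_label=sample_label)
    table.report = report
    return table


_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def _read_shift_star(stream: TextIO, sample_label: str) -> ShiftTable:
    """Minimal NMR-STAR v3 reader: the Atom_chem_shift loop only.

    Tag order inside the loop is free; rows are whitespace-separated.
    This is intentionally not a general STAR parser.
    """
    report = ParseReport()
    records: list[ShiftRecord] = []
    lines = stream.read().splitlines()
    i = 0
    n = len(lines)
    while i < n:
        if lines[i].strip() != "loop_":
            i += 1
            continue
        tags: list[str] = []
        i += 1
        while i < n and lines[i].strip().startswith("_"):
            tags.append(lines[i].strip())
            i += 1
        wanted = {
            "_Atom_chem_shift.Comp_index_ID": None,
            "_Atom_chem_shift.Comp_ID": None,
            "_Atom_chem_shift.Atom_ID": None,
            "_Atom_chem_shift.Val": None,
        }
        for idx, tag in enumerate(tags):
            if tag in wanted:
                wanted[tag] = idx
        if any(v is None for v in wanted.values()):
            # not the shift loop; skip to stop_
            while i < n and lines[i].strip() != "stop_":
                i += 1
            continue
        while i < n and lines[i].strip() != "stop_":
            row = lines[i].split()
            i += 1
            if not row or row[0].startswith("#"):
                continue
            if len(row) < len(tags):
                raise DataError(f"malformed NMR-STAR row at line {i}")
            resnum = int(row[wanted["_Atom_chem_shift.Comp_index_ID"]])
            comp = row[wanted["_Atom_chem_shift.Comp_ID"]].upper()
            atom = row[wanted["_Atom_chem_shift.Atom_ID"]].upper()
            val = float(row[wanted["_Atom_chem_shift.Val"]])
            aa = _THREE_TO_ONE.get(comp, "X")
            if atom not in SUPPORTED_ATOMS:
                report.n_skipped += 1
                report.skipped.append(f"line {i}: unsupported atom {atom}")
                continue
            records.append(ShiftRecord(resnum, aa, atom, val))
            report.n_parsed += 1
    if not records:
        raise DataError("no records: no Atom_chem_shift loop found")
    table = ShiftTable(records, sample_label=sample_label)
    table.report = report
    return table


def write_shift_table(table: ShiftTable, stream: TextIO) -> None:
    stream.write("residue\taa\tatom\tshift_ppm\n")
    for rec in table.records:
        stream.write(f"{rec.residue_number}\t{rec.residue_type}\t{rec.atom}\t{rec.shift:.4f}\n")


# ---------------------------------------------------------------------------
# peak lists and titration manifests


def read_peak_list(source: TextIO | str) -> list[AmidePeak]:
    stream = _as_stream(source)
    header = stream.readline()
    if not header:
        raise DataError("no records: empty peak list")
    if header.rstrip("\n").split("\t") != ["residue", "h_ppm", "n_ppm"]:
        raise DataError(f"bad peak-list header: {header.strip()!r}")
    peaks: list[AmidePeak] = []
    for lineno, line in enumerate(stream, start=2):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 3:
            raise DataError(f"malformed peak-list row at line {lineno}")
        try:
            peaks.append(AmidePeak(int(parts[0]), float(parts[1]), float(parts[2])))
        except ValueError as exc:
            raise DataError(f"malformed peak-list row at line {lineno}: {exc}") from None
    return peaks


def write_peak_list(peaks: Iterable[AmidePeak], stream: TextIO) -> None:
    stream.write("residue\th_ppm\tn_ppm\n")
    for pk in sorted(peaks, key=lambda p: p.residue_number):
        stream.write(f"{pk.residue_number}\t{pk.h_ppm:.4f}\t{pk.n_ppm:.4f}\n")


def read_titration(manifest: TextIO | str, base_dir: str | None = None) -> TitrationSeries:
    """Read a titration manifest and its referenced peak lists.

    Relative peak-list paths are resolved against ``base_dir`` (defaults
    to the manifest's own directory when the manifest is given as a
    path, else the working directory).  Points are returned sorted by
    ligand:protein ratio regardless of manifest order.
    """
    if isinstance(manifest, (str, os.PathLike)):
        if base_dir is None:
            base_dir = os.path.dirname(os.fspath(manifest))
        stream: TextIO = open(manifest, "rt", encoding="utf-8")
        close = True
    else:
        stream = manifest
        close = False
    base_dir = base_dir or "."
    try:
        header = stream.readline()
        if not header:
            raise DataError("no records: empty manifest")
        if header.rstrip("\n").split("\t") != ["p_total_M", "l_total_M", "peaklist_path"]:
            raise DataError(f"bad manifest header: {header.strip()!r}")
        points: list[TitrationPoint] = []
        for lineno, line in enumerate(stream, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise DataError(f"malformed manifest row at line {lineno}")
            p_total = float(parts[0])
            l_total = float(parts[1])
            path = parts[2]
            if not os.path.isabs(path):
                path = os.path.join(base_dir, path)
            with open(path, "rt", encoding="utf-8") as fh:
                peaks = read_peak_list(fh)
            points.append(TitrationPoint(p_total, l_total, peaks))
    finally:
        if close:
            stream.close()
    return TitrationSeries(points)


def write_titration(series: TitrationSeries, out_dir: str, stem: str = "point") -> str:
    """Write a series as manifest + per-point peak lists; returns manifest path."""
    os.makedirs(out_dir, exist_ok=True)
    manifest_path = os.path.join(out_dir, "manifest.tsv")
    with open(manifest_path, "wt", encoding="utf-8") as mh:
        mh.write("p_total_M\tl_total_M\tpeaklist_path\n")
        for i, pt in enumerate(series.points):
            name = f"{stem}_{i:02d}.tsv"
            with open(os.path.join(out_dir, name), "wt", encoding="utf-8") as fh:
                write_peak_list(pt.peaks, fh)
            mh.write(f"{pt.p_total:.6g}\t{pt.l_total:.6g}\t{name}\n")
    return manifest_path


# ---------------------------------------------------------------------------
# alignments


def read_alignment(source: TextIO | str) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`.

    Sequences are uppercased; gaps must be ``-``; any symbol outside
    the 20 amino acids, ``X`` and the gap raises an error.
    """
    stream = _as_stream(source)
    try:
        msa = AlignIO.read(stream, "fasta")
    except ValueError as exc:
        raise DataError(f"cannot read alignment: {exc}") from None
    ids = [rec.id for rec in msa]
    seqs = [str(rec.seq).upper() for rec in msa]
    allowed = _AA_SET | {"-", "X"}
    for ident, seq in zip(ids, seqs):
        bad = set(seq) - allowed
        if bad:
            raise DataError(f"sequence {ident!r} contains invalid symbol {sorted(bad)[0]!r}")
    return Alignment(ids, seqs)


def write_alignment(aln: Alignment, stream: TextIO) -> None:
    for ident, seq in zip(aln.ids, aln.seqs):
        stream.write(f">{ident}\n{seq}\n")


# ---------------------------------------------------------------------------
# PDB painting


def paint_structure(pdb_text: str, scores: Mapping[int, float], default: float = 0.0) -> str:
    """Write per-residue scores into the B-factor column of a PDB file.

    Only columns 61-66 (the isotropic B-factor field) of ATOM/HETATM
    records change; every other byte of the file is preserved, so the
    output can be diffed column-wise against the input.  Scores are
    clipped to [0, 999.99] and formatted to two decimals.  Residues
    without a score get ``default``.
    """
    lines = pdb_text.splitlines(keepends=True)
    n_atoms = 0
    out: list[str] = []
    for line in lines:
        if line.startswith(("ATOM  ", "HETATM")) and len(line.rstrip("\n")) >= 66:
            n_atoms += 1
            try:
                resnum = int(line[22:26])
            except ValueError as exc:
                raise DataError(f"unreadable residue number in PDB line: {line[:26]!r}") from None
            score = float(scores.get(resnum, default))
            score = min(max(score, 0.0), 999.99)
            out.append(line[:60] + f"{score:6.2f}" + line[66:])
        else:
            out.append(line)
    if n_atoms == 0:
        raise DataError("unreadable PDB: no ATOM/HETATM records")
    return "".join(out)


def _as_stream(source: TextIO | str) -> TextIO:
    if isinstance(source, io.TextIOBase):
        return source
    if isinstance(source, (str, os.PathLike)) and os.path.exists(source):
        return open(source, "rt", encoding="utf-8")
    if isinstance(source, str):
        return io.StringIO(source)
    return source
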