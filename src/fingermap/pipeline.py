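"""Run configuration and the end-to-end pipeline driver.

A run is described by a plain-text config file of ``key = value``
lines with dotted keys (``#`` comments allowed).  Stages execute in
order — titration loading, CSP, hotspot calling, Kd fit + bootstrap,
zinc-finger positions, profile scoring, disorder, structure painting —
each only when its inputs are configured.  Every stochastic step is
seeded through the config, so a run is deterministic: running twice
with the same config produces byte-identical reports.  A
``MANIFEST.json`` records the package version, a hash of the resolved
config, the outputs written, and (on failure) the stage that failed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Any, TextIO

from . import __version__
from .csp_analysis import CSPConfig, call_hotspots, csp_from_series
from .binding_model import bootstrap_kd_ci, fit_kd
from .disorder import classify_regions, rci_s2
from .errors import DataError, FingermapError
from .shift_io import (
    paint_structure,
    read_alignment,
    read_shift_table,
    read_titration,
)
from .zf_domain import (
    annotate_c2h2,
    atypicality_score,
    build_profile,
    dna_binding_residues,
    helix_position,
    information_content,
)

log = logging.getLogger("fingermap")

_KNOWN_KEYS = {
    "series.manifest",
    "csp.alpha_n",
    "hotspot.method",
    "hotspot.k",
    "hotspot.q",
    "fit.enabled",
    "fit.fix_free_shifts",
    "boot.n",
    "boot.seed",
    "zf.fasta",
    "zf.start",
    "profile.alignment",
    "profile.pseudocount",
    "disorder.shifts",
    "disorder.dialect",
    "disorder.window",
    "disorder.cutoff",
    "structure.pdb",
    "out.dir",
}

_DEFAULTS: dict[str, Any] = {
    "csp.alpha_n": 0.14,
    "hotspot.method": "ksd",
    "hotspot.k": 1.0,
    "hotspot.q": 0.9,
    "fit.enabled": True,
    "fit.fix_free_shifts": True,
    "boot.n": 200,
    "boot.seed": 0,
    "zf.start": 1,
    "profile.pseudocount": 1.0,
    "disorder.dialect": "tsv",
    "disorder.window": 3,
    "disorder.cutoff": 0.7,
    "out.dir": "fingermap_run",
}

_FLOAT_KEYS = {"csp.alpha_n", "hotspot.k", "hotspot.q", "profile.pseudocount", "disorder.cutoff"}
_INT_KEYS = {"boot.n", "boot.seed", "zf.start", "disorder.window"}
_BOOL_KEYS = {"fit.enabled", "fit.fix_free_shifts"}


@dataclass
class RunConfig:
    """Validated, fully resolved pipeline configuration."""

    values: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.values) - _KNOWN_KEYS
        if unknown:
            raise DataError(f"unknown config key {sorted(unknown)[0]!r}")
        resolved = dict(_DEFAULTS)
        resolved.update(self.values)
        self.values = resolved

    def __getitem__(self, key: str) -> Any:
        return self.values[key]

    def get(self, key: str, default: Any = None) -> Any:
        return self.values.get(key, default)

    def digest(self) -> str:
        blob = json.dumps(self.values, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def parse_config(stream: TextIO | str) -> RunConfig:
    """Parse ``key = value`` lines with dotted keys into a RunConfig."""
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = stream.read().splitlines()
    values: dict[str, Any] = {}
    for lineno, line in enumerate(lines, start=1):
        text = line.split("#", 1)[0].strip()
        if not text:
            continue
        if "=" not in text:
            raise DataError(f"config line {lineno}: expected 'key = value'")
        key, _, raw = text.partition("=")
        key = key.strip()
        raw = raw.strip()
        if key not in _KNOWN_KEYS:
            raise DataError(f"unknown config key {key!r} (line {lineno})")
        if key in _FLOAT_KEYS:
            values[key] = float(raw)
        elif key in _INT_KEYS:
            values[key] = int(raw)
        elif key in _BOOL_KEYS:
            if raw.lower() not in {"true", "false", "yes", "no", "1", "0"}:
                raise DataError(f"config line {lineno}: boolean expected")
            values[key] = raw.lower() in {"true", "yes", "1"}
        else:
            values[key] = raw
    return RunConfig(values)


def _write_tsv(path: str, header: list[str], rows: list[list[Any]]) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute all configured stages; returns the manifest dict.

    Stage failures raise :class:`FingermapError` with the stage name
    prefixed; outputs produced before the failure are kept and listed
    in ``MANIFEST.json`` together with the failure point.
    """
    out_dir = config["out.dir"]
    os.makedirs(out_dir, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "config_hash": config.digest(),
        "config": config.values,
        "outputs": [],
        "failed_stage": None,
    }

    def emit(name: str) -> str:
        path = os.path.join(out_dir, name)
        manifest["outputs"].append(name)
        return path

    stage = "config"
    try:
        series = None
        profile = None
        hotspots = None
        if config.get("series.manifest"):
            stage = "load-series"
            log.info("loading titration series from %s", config["series.manifest"])
            series = read_titration(config["series.manifest"])

            stage = "csp"
            cfg = CSPConfig(alpha_n=config["csp.alpha_n"])
            profile = csp_from_series(series, cfg)
            rel = profile.relative()

            stage = "hotspots"
            hotspots = call_hotspots(
                profile,
                method=config["hotspot.method"],
                k=config["hotspot.k"],
                q=config["hotspot.q"],
            )
            rows = [
                [r, f"{v:.5f}", f"{rel[r]:.4f}", int(r in hotspots.hotspots)]
                for r, v in sorted(profile.values.items())
            ]
            _write_tsv(emit("csp.tsv"), ["residue", "csp_ppm", "relative_csp", "hotspot"], rows)
            with open(emit("hotspots.json"), "wt", encoding="utf-8") as fh:
                json.dump(
                    {
                        "method": hotspots.method,
                        "threshold_ppm": hotspots.threshold_value,
                        "hotspots": sorted(hotspots.hotspots),
                    },
                    fh,
                    indent=1,
                    sort_keys=True,
                )

            if config["fit.enabled"]:
                stage = "fitkd"
                fit = fit_kd(
                    series,
                    fix_free_shifts=config["fit.fix_free_shifts"],
                    alpha_n=config["csp.alpha_n"],
                )
                if config["boot.n"] >= 100 and len(fit.residues_used) >= 3:
                    bootstrap_kd_ci(series, fit, n_boot=config["boot.n"], seed=config["boot.seed"])
                with open(emit("binding_fit.json"), "wt", encoding="utf-8") as fh:
                    json.dump(
                        {
                            "kd_M": fit.kd_hat,
                            "kd_ci_M": list(fit.kd_ci) if fit.kd_ci else None,
                            "rss": fit.rss,
                            "n_points_used": fit.n_points_used,
                            "message": fit.message,
                            "alpha_n": fit.alpha_n,
                            "delta_bound_ppm": {
                                str(r): list(v) for r, v in sorted(fit.delta_bound.items())
                            },
                            "bootstrap_seed": fit.bootstrap_seed,
                        },
                        fh,
                        indent=1,
                        sort_keys=True,
                    )

        annotations = []
        if config.get("zf.fasta"):
            stage = "zfpos"
            aln = read_alignment(config["zf.fasta"])
            seq = aln.seqs[0].replace("-", "")
            annotations = annotate_c2h2(seq, start=config["zf.start"])
            rows = []
            for ann in annotations:
                for resnum in range(ann.start, ann.end + 1):
                    pos = helix_position(resnum, ann)
                    rows.append([resnum, ann.residue_type(resnum), str(pos)])
                for pos, (resnum, aa) in dna_binding_residues(ann).items():
                    log.info("DNA-binding position %+d: %s%d", pos, aa, resnum)
            _write_tsv(emit("zf_positions.tsv"), ["residue", "aa", "helix_position"], rows)

        if config.get("profile.alignment") and annotations:
            stage = "profile"
            aln = read_alignment(config["profile.alignment"])
            prof = build_profile(aln, pseudocount=config["profile.pseudocount"])
            ic = information_content(prof)
            ann = annotations[0]
            # map helix positions onto alignment columns assuming the
            # alignment is the finger itself, columns 0..width-1
            column_map = {}
            for pos in (-1, 1, 2, 3, 6):
                from .zf_domain import residue_at_position

                resnum = residue_at_position(ann, pos)
                col = resnum - ann.start
                if 0 <= col < prof.width:
                    column_map[pos] = col
            score = None
            if len(column_map) == 5:
                score = atypicality_score(ann, prof, column_map, seed=config["boot.seed"])
            with open(emit("profile.json"), "wt", encoding="utf-8") as fh:
                json.dump(
                    {
                        "width": prof.width,
                        "information_content_bits": [float(x) for x in ic],
                        "columns": prof.columns.tolist(),
                        "background": prof.background.tolist(),
                        "atypicality": None
                        if score is None
                        else {
                            "per_position": {str(k): v for k, v in score.per_position.items()},
                            "total": score.total,
                            "percentile": score.percentile,
                        },
                    },
                    fh,
                    indent=1,
                    sort_keys=True,
                )

        if config.get("disorder.shifts"):
            stage = "disorder"
            table = read_shift_table(config["disorder.shifts"], dialect=config["disorder.dialect"])
            dprof = rci_s2(table, window=config["disorder.window"])
            regions = classify_regions(dprof, s2_cutoff=config["disorder.cutoff"])
            labels = {}
            for start, end, lab in regions:
                for r in range(start, end + 1):
                    labels[r] = lab
            rows = [
                [r, f"{dprof.rci[r]:.4f}", f"{dprof.s2[r]:.4f}", labels.get(r, "NA")]
                for r in dprof.residues
            ]
            _write_tsv(emit("disorder.tsv"), ["residue", "rci", "s2", "region"], rows)

        if config.get("structure.pdb") and profile is not None:
            stage = "paint"
            with open(config["structure.pdb"], "rt", encoding="utf-8") as fh:
                pdb_text = fh.read()
            painted = paint_structure(pdb_text, profile.values, default=0.0)
            with open(emit("painted.pdb"), "wt", encoding="utf-8") as fh:
                fh.write(painted)

        stage = "manifest"
    except (FingermapError, OSError) as exc:
        manifest["failed_stage"] = stage
        with open(os.path.join(out_dir, "MANIFEST.json"), "wt", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        raise FingermapError(f"[{stage}] {exc}") from exc

    with open(os.path.join(out_dir, "MANIFEST.json"), "wt", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
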