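"""File formats, run configuration, and report writing.

Formats
-------
* Protein sequences: standard FASTA.
* Modification rules: tab-separated text with columns
  ``rule_id  target_residue  mode  mass_Da  label`` where mode is ``replace``
  (absolute modified mass) or ``shift`` (additive mass shift); ``#`` starts a
  comment.
* Spectra: plain text with a ``PRECURSOR_MASS=<Da>`` header line followed by
  one deconvoluted prefix mass in Dalton per line; ``#`` starts a comment.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import pandas as pd
import yaml
from Bio import SeqIO

from . import __version__
from .align import Alignment
from .masses import ModificationRule
from .mass_graph import PMG, SMG
from .metrics import AlignmentMetrics


class FormatError(ValueError):
    """A file failed to parse; the message names the offending line."""


def read_fasta(path) -> List[Tuple[str, str]]:
    """Read (id, sequence) pairs from a FASTA file."""
    records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(path, records: Sequence[Tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for off in range(0, len(seq), 60):
                fh.write(seq[off : off + 60] + "\n")


def read_rules(path) -> List[ModificationRule]:
    rules: List[ModificationRule] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(
                    f"{path}:{lineno}: expected at least 4 tab-separated fields"
                )
            rule_id, target, mode, mass = parts[:4]
            label = parts[4] if len(parts) > 4 else ""
            try:
                rules.append(
                    ModificationRule(rule_id, target, mode, float(mass), label)
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    if not rules:
        raise FormatError(f"{path}: no modification rules found")
    return rules


def write_rules(path, rules: Sequence[ModificationRule]) -> None:
    with open(path, "w") as fh:
        fh.write("# rule_id\ttarget_residue\tmode\tmass_Da\tlabel\n")
        for r in rules:
            fh.write(f"{r.rule_id}\t{r.target}\t{r.mode}\t{r.mass_da}\t{r.label}\n")


def read_spectrum(path) -> Tuple[List[float], Optional[float]]:
    """Read (peak masses in Da, precursor mass or None) from a spectrum file."""
    peaks: List[float] = []
    precursor: Optional[float] = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if line.upper().startswith("PRECURSOR_MASS"):
                try:
                    precursor = float(line.split("=", 1)[1])
                except (IndexError, ValueError) as exc:
                    raise FormatError(f"{path}:{lineno}: bad precursor header") from exc
                continue
            try:
                peaks.append(float(line))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: not a peak mass: {line!r}") from exc
    return peaks, precursor


def write_spectrum(path, peaks: Sequence[float], precursor: Optional[float]) -> None:
    with open(path, "w") as fh:
        if precursor is not None:
            fh.write(f"PRECURSOR_MASS={precursor!r}\n")
        for p in peaks:
            fh.write(f"{p!r}\n")


@dataclass
class RunConfig:
    """Every tunable of an alignment run; defaults match the library defaults."""

    tolerance_mode: str = "fixed"  # fixed | peak_dependent
    delta: int = 27
    ppm: float = 15.0
    add_complementary: bool = True
    satellite_threshold_da: float = 5000.0
    max_gap_residues: int = 10
    max_red_edges: int = 2
    mode: str = "global"  # global | diagonal
    start_node: Optional[int] = None
    start_peak: Optional[int] = None
    band: Optional[int] = None
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.tolerance_mode not in ("fixed", "peak_dependent"):
            raise ValueError(f"unknown tolerance mode {self.tolerance_mode!r}")
        if self.mode not in ("global", "diagonal"):
            raise ValueError(f"unknown alignment mode {self.mode!r}")
        if self.mode == "diagonal" and (self.start_node is None or self.start_peak is None):
            raise ValueError("diagonal mode requires start_node and start_peak")
        if self.delta < 0 or self.ppm < 0 or self.max_gap_residues < 1 or self.max_red_edges < 0:
            raise ValueError("invalid tolerance/cap settings")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
    cfg = RunConfig(**data)
    cfg.validate()
    return cfg


def alignment_table(a: Alignment, pmg: PMG, smg: SMG) -> pd.DataFrame:
    """One row per matched triple, plus sub-path annotation of each step."""
    rows = []
    for q in range(a.size):
        i, j, k = a.peaks[q], a.nodes[q], a.corrections[q]
        rows.append(
            {
                "node": j,
                "residue_index": j,  # 1-based residue p is covered by position p
                "peak": i,
                "raw_mass": int(smg.masses[i]),
                "corrected_mass": int(smg.masses[i]) + k,
                "k": k,
                "subpath_mass": a.step_masses[q - 1] if q > 0 else "",
                "residues_spanned": (a.nodes[q] - a.nodes[q - 1]) if q > 0 else "",
            }
        )
    return pd.DataFrame.from_records(rows)


def write_report(
    a: Alignment,
    metrics: AlignmentMetrics,
    cfg: RunConfig,
    out_prefix,
    pmg: PMG,
    smg: SMG,
) -> Tuple[Path, Path]:
    """Write the TSV triple table and the JSON summary; returns both paths."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    tsv_path = out_prefix.with_suffix(".tsv")
    json_path = out_prefix.with_suffix(".json")
    alignment_table(a, pmg, smg).to_csv(tsv_path, sep="\t", index=False)
    summary = {
        "tool": "mgalign",
        "version": __version__,
        "config": cfg.to_dict(),
        **metrics.to_json(),
    }
    with open(json_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return tsv_path, json_path
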