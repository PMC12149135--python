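"""Reading candidate Nm sites and assembling fixed-length windows.

Inputs are a FASTA of parent sequences (DNA T is transcribed to U on the
fly) and a TSV site table with a header row and columns
``seq_id  center  subtype  label``. Coordinates are 0-based; pass
``one_based=True`` (CLI flag ``--one-based``) to shift input centers by -1.

Windows extend ``flank`` bases either side of the candidate (default 25,
i.e. 51-nt windows). Records whose window would overrun the parent
sequence are dropped with a logged count; duplicate (seq_id, center) rows
keep the first occurrence.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .encoders import AlphabetError, DotBracketError, parse_dotbracket

logger = logging.getLogger("nmfuse")

SUBTYPES = ("Am", "Cm", "Gm", "Um")
DEFAULT_FLANK = 25


@dataclass(frozen=True)
class SiteRecord:
    """One candidate 2'-O-methylation site on a parent sequence."""

    seq_id: str
    center: int          # 0-based position of the candidate nucleotide
    subtype: str         # Am / Cm / Gm / Um
    label: int           # 1 positive, 0 negative


@dataclass
class Window:
    """A fixed-length subsequence centered on a candidate site."""

    bases: str
    dotbracket: str | None = None
    origin: SiteRecord | None = None

    def __len__(self):
        return len(self.bases)


def read_fasta(path) -> dict[str, str]:
    """Parse a FASTA into {id: sequence}, uppercased, T transcribed to U."""
    seqs = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = str(rec.seq).upper().replace("T", "U")
    if not seqs:
        raise ValueError(f"no FASTA records found in {path}")
    return seqs


def read_sites(fasta_path, site_table_path, flank: int = DEFAULT_FLANK,
               one_based: bool = False) -> list[SiteRecord]:
    """Read the site table, validating against the FASTA.

    Rows whose window [center - flank, center + flank] overruns the parent
    sequence are dropped (count logged); duplicate (seq_id, center) rows
    keep the first. A seq_id absent from the FASTA, a malformed row, or a
    positive record whose center base contradicts its subtype is a hard
    error.
    """
    seqs = read_fasta(fasta_path)
    table = pd.read_csv(site_table_path, sep="\t", dtype=str)
    required = {"seq_id", "center", "subtype", "label"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"site table missing column(s): {sorted(missing)}")

    records: list[SiteRecord] = []
    seen: set[tuple[str, int]] = set()
    dropped = 0
    for line_no, row in enumerate(table.itertuples(index=False), start=2):
        try:
            center = int(row.center) - (1 if one_based else 0)
            subtype = str(row.subtype)
            label = int(row.label)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed site-table row at line {line_no}: {exc}") from exc
        if subtype not in SUBTYPES:
            raise ValueError(f"unknown subtype '{subtype}' at line {line_no}")
        if label not in (0, 1):
            raise ValueError(f"label must be 0 or 1 at line {line_no}")
        seq_id = str(row.seq_id)
        if seq_id not in seqs:
            raise KeyError(f"seq_id '{seq_id}' (line {line_no}) not present in FASTA")
        parent = seqs[seq_id]
        if center - flank < 0 or center + flank >= len(parent):
            dropped += 1
            continue
        if label == 1 and parent[center] != subtype[0]:
            raise ValueError(
                f"positive site at line {line_no}: center base "
                f"'{parent[center]}' does not match subtype {subtype}")
        key = (seq_id, center)
        if key in seen:
            continue
        seen.add(key)
        records.append(SiteRecord(seq_id, center, subtype, label))
    if dropped:
        logger.info("read_sites: dropped %d record(s) whose %d-nt window "
                    "overruns the parent sequence", dropped, 2 * flank + 1)
    return records


def extract_window(record: SiteRecord, parent_sequence: str,
                   flank: int = DEFAULT_FLANK) -> Window:
    """Cut the [center - flank, center + flank] window around a site."""
    if flank < 1:
        raise ValueError("flank must be >= 1")
    seq = parent_sequence.upper().replace("T", "U")
    lo, hi = record.center - flank, record.center + flank
    if lo < 0 or hi >= len(seq):
        raise IndexError(
            f"window [{lo}, {hi}] overruns sequence of length {len(seq)}")
    bases = seq[lo:hi + 1]
    bad = set(bases) - set("ACGUN")
    if bad:
        raise AlphabetError(f"illegal base(s) {sorted(bad)} in window")
    return Window(bases=bases, origin=record)


def load_windows(fasta_path, site_table_path, flank: int = DEFAULT_FLANK,
                 one_based: bool = False) -> list[Window]:
    """read_sites + extract_window in one call."""
    seqs = read_fasta(fasta_path)
    records = read_sites(fasta_path, site_table_path, flank, one_based)
    return [extract_window(r, seqs[r.seq_id], flank) for r in records]


def _validate_structure(window: Window, db: str, index: int) -> None:
    if len(db) != len(window.bases):
        raise ValueError(
            f"structure for window {index}: length {len(db)} != "
            f"window length {len(window.bases)}")
    try:
        parse_dotbracket(db)
    except DotBracketError as exc:
        raise DotBracketError(f"structure for window {index}: {exc}") from exc


def attach_structures(windows, source) -> list[Window]:
    """Attach one dot-bracket string per window, in order.

    ``source`` is either a path to a plain-text file with one structure per
    line, or a callable mapping a window's bases to a dot-bracket string
    (e.g. :func:`rnafold_hook` or ``encoders.fold_nussinov``). Structures
    are validated for length and balanced brackets.
    """
    if callable(source):
        structures = [source(w.bases) for w in windows]
    else:
        lines = Path(source).read_text().splitlines()
        structures = [ln.strip() for ln in lines if ln.strip()]
        if len(structures) != len(windows):
            raise ValueError(
                f"{len(structures)} structures for {len(windows)} windows")
    for i, (w, db) in enumerate(zip(windows, structures)):
        _validate_structure(w, db, i)
        w.dotbracket = db
    return windows


def rnafold_hook(bases: str) -> str:
    """Fold one window by shelling out to ``RNAfold --noPS``.

    Requires the ViennaRNA RNAfold executable on PATH; the dot-bracket is
    parsed from the second output line.
    """
    if shutil.which("RNAfold") is None:
        raise RuntimeError("RNAfold not found on PATH")
    proc = subprocess.run(
        ["RNAfold", "--noPS"], input=bases + "\n", text=True,
        capture_output=True, check=True)
    lines = proc.stdout.splitlines()
    if len(lines) < 2:
        raise RuntimeError(f"unexpected RNAfold output: {proc.stdout!r}")
    return lines[1].split()[0].strip()
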