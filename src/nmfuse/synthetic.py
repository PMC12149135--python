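"""Synthetic Nm-like benchmark data with plantable class signal.

Generates balanced positive/negative windows (default 51 nt) in which the
class difference can be placed, independently, in any of the three feature
views:

* sequence — a (possibly IUPAC-degenerate) motif written at a fixed offset
  in a tunable fraction of positives;
* chemistry — the motif letters carry chemical-property bits, so a planted
  sequence motif also biases the chemical view;
* structure — a complementary stem planted around the center of positives,
  so the maximum-pairing folder produces a hairpin enclosing the candidate
  site, while negatives fold like random sequence.

Negatives are i.i.d. uniform bases whose center base matches the assigned
subtype (hard negatives: the center nucleotide alone carries no signal).
Subtype frequencies default to the published composition of the
single-base-resolution Nm catalog (Am 22.1%, Cm 26.1%, Gm 20.5%,
Um 31.3%).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .data_io import SiteRecord, Window
from .encoders import fold_nussinov

# Published per-subtype counts of the Nm catalog the default proportions
# derive from, plus the per-subtype positive counts of its held-out test set.
NM_SITE_COUNTS = {"Am": 1591, "Cm": 1878, "Gm": 1471, "Um": 2253}
NM_TEST_POSITIVES = {"Am": 352, "Cm": 490, "Gm": 300, "Um": 706}

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "R": "AG", "Y": "CU", "S": "CG", "W": "AU", "K": "GU", "M": "AC",
    "B": "CGU", "D": "AGU", "H": "ACU", "V": "ACG", "N": "ACGU",
}
_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}


def dataset_composition() -> dict[str, float]:
    """Bookkeeping arithmetic of the balanced catalog design.

    From the per-subtype positive counts: total positives, per-subtype
    percentages, and the balanced test/train sample totals implied by the
    held-out per-subtype test positives.
    """
    total_pos = sum(NM_SITE_COUNTS.values())
    test_pos = sum(NM_TEST_POSITIVES.values())
    out = {"total_positive_sites": float(total_pos)}
    for subtype, count in NM_SITE_COUNTS.items():
        out[f"{subtype.lower()}_pct"] = round(100.0 * count / total_pos, 1)
    out["test_sample_total"] = float(2 * test_pos)
    out["train_sample_total"] = float(2 * (total_pos - test_pos))
    return out


@dataclass
class SynthSpec:
    """Generator settings; defaults are the benchmark's study conditions."""

    n_per_class: int = 1000
    window_len: int = 51
    subtype_props: dict = field(default_factory=lambda: {
        "Am": 0.221, "Cm": 0.261, "Gm": 0.205, "Um": 0.313})
    motif: str = "GGACU"
    motif_pos: int = 23
    motif_strength: float = 0.9
    struct_signal: float = 0.0
    stem_len: int = 8
    stem_gap: int = 6          # unpaired bases between stem arm and center
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.subtype_props.values()) - 1.0) > 1e-9:
            raise ValueError("subtype proportions must sum to 1")
        if self.window_len % 2 == 0 or self.window_len < 5:
            raise ValueError("window_len must be odd and >= 5")
        if self.motif_pos < 0 or self.motif_pos + len(self.motif) > self.window_len:
            raise ValueError("motif overruns the window")
        if not (0.0 <= self.motif_strength <= 1.0 and 0.0 <= self.struct_signal <= 1.0):
            raise ValueError("signal strengths must lie in [0, 1]")
        if self.struct_signal > 0:
            reach = self.stem_gap + self.stem_len
            if self.window_len // 2 - reach < 0:
                raise ValueError("planted stem overruns the window")
        bad = set(self.motif) - set(_IUPAC)
        if bad:
            raise ValueError(f"motif has non-IUPAC letter(s) {sorted(bad)}")


def _random_bases(rng, n):
    return rng.choice(list("ACGU"), size=n)


def _make_window(rng, spec: SynthSpec, subtype: str, positive: bool) -> str:
    L = spec.window_len
    center = L // 2
    bases = _random_bases(rng, L)
    if positive and rng.random() < spec.motif_strength:
        for off, letter in enumerate(spec.motif):
            bases[spec.motif_pos + off] = rng.choice(list(_IUPAC[letter]))
    if positive and rng.random() < spec.struct_signal:
        arm = _random_bases(rng, spec.stem_len)
        left = center - spec.stem_gap - spec.stem_len
        right = center + spec.stem_gap + 1
        bases[left:left + spec.stem_len] = arm
        bases[right:right + spec.stem_len] = [_COMPLEMENT[b] for b in arm[::-1]]
    bases[center] = subtype[0]
    return "".join(bases)


def generate(spec: SynthSpec) -> list[tuple[Window, int, str]]:
    """Generate a balanced labeled set of folded windows.

    Returns (Window, label, subtype) triples; each window has its
    dot-bracket structure attached (maximum-pairing fold). Deterministic
    under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    subtype_names = list(spec.subtype_props)
    props = np.array([spec.subtype_props[s] for s in subtype_names])
    pos_subtypes = rng.choice(subtype_names, size=spec.n_per_class, p=props)
    neg_subtypes = rng.permutation(pos_subtypes)  # mirror the composition

    samples: list[tuple[Window, int, str]] = []
    flank = spec.window_len // 2
    idx = 0
    for label, subtypes in ((1, pos_subtypes), (0, neg_subtypes)):
        for subtype in subtypes:
            bases = _make_window(rng, spec, subtype, positive=label == 1)
            record = SiteRecord(seq_id=f"w{idx:06d}", center=flank,
                                subtype=str(subtype), label=label)
            window = Window(bases=bases, dotbracket=fold_nussinov(bases),
                            origin=record)
            samples.append((window, label, str(subtype)))
            idx += 1
    return samples


def write_fixture(samples, out_dir) -> dict[str, Path]:
    """Write FASTA + site TSV + dot-bracket files that round-trip data_io."""
    if not samples:
        raise ValueError("no samples to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta = out_dir / "windows.fasta"
    table = out_dir / "sites.tsv"
    structs = out_dir / "structures.txt"

    records = [
        SeqRecord(Seq(w.bases), id=w.origin.seq_id, description="")
        for w, _, _ in samples
    ]
    SeqIO.write(records, str(fasta), "fasta")
    with open(table, "w") as fh:
        fh.write("seq_id\tcenter\tsubtype\tlabel\n")
        for w, label, subtype in samples:
            fh.write(f"{w.origin.seq_id}\t{w.origin.center}\t{subtype}\t{label}\n")
    with open(structs, "w") as fh:
        for w, _, _ in samples:
            if w.dotbracket is None:
                raise ValueError(f"window {w.origin.seq_id} has no structure")
            fh.write(w.dotbracket + "\n")
    return {"fasta": fasta, "sites": table, "structures": structs}
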