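"""Feature views for 51-nt candidate windows.

Each window is turned into three matrices:

* ``x_seq``  (L x 4)  — one-hot base identity, column order A, C, G, U;
* ``x_chem`` (L x 3)  — chemical-property bits: (ring count class,
  amino vs. keto group, weak vs. strong base pairing), so
  A=(1,1,1), C=(0,1,0), G=(1,0,0), U=(0,0,1);
* ``x_str``  (L x L)  — symmetric binary base-pair matrix derived from a
  dot-bracket string: entry (i, j) = (j, i) = 1 iff bases i and j pair.

`N` encodes to an all-zero row in both per-base views.

A maximum-pairing Nussinov folder (AU/GC/GU pairs, minimum hairpin loop 3)
is provided so structures can be produced without an external
thermodynamic folder; it is deliberately simple and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

ALPHABET = "ACGU"
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3}
# x: purine ring count; y: amino group; z: weak (A/U) pairing
_CHEM_CODE = {
    "A": (1, 1, 1),
    "C": (0, 1, 0),
    "G": (1, 0, 0),
    "U": (0, 0, 1),
    "N": (0, 0, 0),
}
_BRACKET_PAIRS = {"(": ")", "[": "]", "{": "}"}
_CLOSERS = {v: k for k, v in _BRACKET_PAIRS.items()}


class AlphabetError(ValueError):
    """A base outside {A, C, G, U, N} was encountered."""


class DotBracketError(ValueError):
    """Malformed dot-bracket notation."""


@dataclass
class EncodedSample:
    """The three feature views of one window, plus its label.

    ``x_node`` carries the graph node features (one-hot base identity) used
    by the structure branch; it equals ``x_seq`` for real encodings but is a
    separate array so the sequence view can be ablated independently.
    """

    x_seq: np.ndarray   # (L, 4) binary
    x_chem: np.ndarray  # (L, 3) binary
    x_str: np.ndarray   # (L, L) binary symmetric, zero diagonal
    x_node: np.ndarray  # (L, 4) binary, GAT node features
    label: int


def _check_alphabet(bases: str) -> None:
    bad = set(bases) - set("ACGUN")
    if bad:
        raise AlphabetError(f"illegal base(s) {sorted(bad)} in window")


def encode_onehot(bases: str) -> np.ndarray:
    """One-hot encode a window; N maps to an all-zero row."""
    _check_alphabet(bases)
    out = np.zeros((len(bases), 4), dtype=np.int8)
    for i, b in enumerate(bases):
        if b != "N":
            out[i, _BASE_INDEX[b]] = 1
    return out


def encode_chemical(bases: str) -> np.ndarray:
    """3-bit chemical-property encoding; N maps to an all-zero row."""
    _check_alphabet(bases)
    return np.array([_CHEM_CODE[b] for b in bases], dtype=np.int8)


def decode_chemical(row) -> str:
    """Invert the chemical code for a single (x, y, z) triple."""
    triple = tuple(int(v) for v in row)
    for base, code in _CHEM_CODE.items():
        if code == triple and base != "N":
            return base
    raise ValueError(f"no base has chemical code {triple}")


def parse_dotbracket(db: str) -> list[tuple[int, int]]:
    """Stack-match a dot-bracket string into a sorted list of (i, j), i < j.

    Round, square and curly bracket families are matched independently.
    """
    stacks: dict[str, list[int]] = {k: [] for k in _BRACKET_PAIRS}
    pairs: list[tuple[int, int]] = []
    for pos, ch in enumerate(db):
        if ch == ".":
            continue
        if ch in _BRACKET_PAIRS:
            stacks[ch].append(pos)
        elif ch in _CLOSERS:
            opener = _CLOSERS[ch]
            if not stacks[opener]:
                raise DotBracketError(f"unmatched '{ch}' at position {pos}")
            pairs.append((stacks[opener].pop(), pos))
        else:
            raise DotBracketError(f"illegal character '{ch}' at position {pos}")
    for opener, stack in stacks.items():
        if stack:
            raise DotBracketError(f"unmatched '{opener}' at position {stack[-1]}")
    return sorted(pairs)


def pairs_to_matrix(pairs, L: int) -> np.ndarray:
    """Binary symmetric L x L base-pair matrix from a pair list."""
    m = np.zeros((L, L), dtype=np.int8)
    for i, j in pairs:
        if not (0 <= i < L and 0 <= j < L):
            raise IndexError(f"pair ({i}, {j}) outside sequence of length {L}")
        m[i, j] = m[j, i] = 1
    return m


# --------------------------------------------------------- Nussinov folding

_CAN_PAIR = np.zeros((4, 4), dtype=np.bool_)
for _a, _b in ("AU", "UA", "GC", "CG", "GU", "UG"):
    _CAN_PAIR[_BASE_INDEX[_a], _BASE_INDEX[_b]] = True


@njit(cache=False)
def _nussinov_table(codes, can_pair, min_loop):  # pragma: no cover - numba
    L = codes.shape[0]
    D = np.zeros((L, L), dtype=np.int32)
    for span in range(min_loop + 1, L):
        for i in range(L - span):
            j = i + span
            best = D[i + 1, j]
            if D[i, j - 1] > best:
                best = D[i, j - 1]
            if codes[i] >= 0 and codes[j] >= 0 and can_pair[codes[i], codes[j]]:
                v = D[i + 1, j - 1] + 1
                if v > best:
                    best = v
            for k in range(i + 1, j):
                v = D[i, k] + D[k + 1, j]
                if v > best:
                    best = v
            D[i, j] = best
    return D


def _traceback(D, codes, min_loop):
    """Deterministic traceback preferring to pair i with the smallest j."""
    L = len(codes)
    pairs = []
    stack = [(0, L - 1)]
    while stack:
        i, j = stack.pop()
        while i < j:
            if D[i, j] == 0:
                break
            paired = False
            for k in range(i + min_loop + 1, j + 1):
                if codes[i] >= 0 and codes[k] >= 0 and _CAN_PAIR[codes[i], codes[k]]:
                    inner = D[i + 1, k - 1] if k - 1 > i + 1 else 0
                    right = D[k + 1, j] if k + 1 <= j else 0
                    if inner + 1 + right == D[i, j]:
                        pairs.append((i, k))
                        if k + 1 <= j:
                            stack.append((k + 1, j))
                        i, j = i + 1, k - 1
                        paired = True
                        break
            if not paired:
                i += 1
    return sorted(pairs)


def fold_nussinov(bases: str, min_loop: int = 3) -> str:
    """Maximum base-pairing fold as a dot-bracket string.

    Allowed pairs: AU, GC and the GU wobble; hairpin loops must span at
    least ``min_loop`` unpaired positions. N never pairs. The traceback is
    deterministic: position i pairs with the smallest admissible partner.
    """
    _check_alphabet(bases)
    L = len(bases)
    if L < min_loop + 2:
        return "." * L
    codes = np.array([_BASE_INDEX.get(b, -1) for b in bases], dtype=np.int8)
    D = _nussinov_table(codes, _CAN_PAIR, min_loop)
    db = ["."] * L
    for i, j in _traceback(D, codes, min_loop):
        db[i], db[j] = "(", ")"
    return "".join(db)


# -------------------------------------------------------- window -> sample

def encode_window(window, label: int | None = None) -> EncodedSample:
    """Encode a Window (with dot-bracket attached) into the three views."""
    bases = window.bases
    if window.dotbracket is None:
        raise ValueError("window has no secondary structure attached")
    if len(window.dotbracket) != len(bases):
        raise ValueError("dot-bracket length differs from window length")
    x_seq = encode_onehot(bases)
    x_str = pairs_to_matrix(parse_dotbracket(window.dotbracket), len(bases))
    if label is None:
        label = window.origin.label if window.origin is not None else 0
    return EncodedSample(
        x_seq=x_seq,
        x_chem=encode_chemical(bases),
        x_str=x_str,
        x_node=x_seq.copy(),
        label=int(label),
    )


class Dataset:
    """Stacked feature arrays for a set of encoded windows."""

    def __init__(self, x_seq, x_chem, x_str, x_node, labels, subtypes=None):
        self.x_seq = np.asarray(x_seq, dtype=np.float32)
        self.x_chem = np.asarray(x_chem, dtype=np.float32)
        self.x_str = np.asarray(x_str, dtype=np.float32)
        self.x_node = np.asarray(x_node, dtype=np.float32)
        self.labels = np.asarray(labels, dtype=np.int64)
        self.subtypes = None if subtypes is None else np.asarray(subtypes)
        n = len(self.labels)
        if not (len(self.x_seq) == len(self.x_chem) == len(self.x_str) == n):
            raise ValueError("feature arrays and labels disagree in length")

    def __len__(self):
        return len(self.labels)

    @property
    def window_len(self):
        return self.x_seq.shape[1]

    def subset(self, idx) -> "Dataset":
        idx = np.asarray(idx)
        return Dataset(
            self.x_seq[idx], self.x_chem[idx], self.x_str[idx],
            self.x_node[idx], self.labels[idx],
            None if self.subtypes is None else self.subtypes[idx],
        )

    def save_npz(self, path):
        np.savez_compressed(
            path, x_seq=self.x_seq.astype(np.int8),
            x_chem=self.x_chem.astype(np.int8),
            x_str=self.x_str.astype(np.int8),
            x_node=self.x_node.astype(np.int8),
            label=self.labels,
            subtype=self.subtypes if self.subtypes is not None else np.array([]),
        )

    @classmethod
    def load_npz(cls, path) -> "Dataset":
        with np.load(path, allow_pickle=False) as z:
            sub = z["subtype"] if z["subtype"].size else None
            return cls(z["x_seq"], z["x_chem"], z["x_str"], z["x_node"],
                       z["label"], sub)


def encode_dataset(samples) -> Dataset:
    """Stack (Window, label, subtype) triples or EncodedSamples into a Dataset."""
    enc, labels, subtypes = [], [], []
    for item in samples:
        if isinstance(item, EncodedSample):
            enc.append(item)
            labels.append(item.label)
            subtypes.append("NA")
        else:
            window, label, subtype = item
            enc.append(encode_window(window, label))
            labels.append(label)
            subtypes.append(subtype)
    return Dataset(
        np.stack([e.x_seq for e in enc]),
        np.stack([e.x_chem for e in enc]),
        np.stack([e.x_str for e in enc]),
        np.stack([e.x_node for e in enc]),
        labels,
        subtypes,
    )
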