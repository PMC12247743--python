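"""tcrdist-style CDR3 pairwise distances.

CDR3 loops are trimmed (3 residues from the N-terminus, 2 from the
C-terminus by default — the conserved flanks contribute little to antigen
contact), then compared position-wise with a capped BLOSUM62-derived
residue distance d(a,b) = max(0, min(4, 4 − BLOSUM62(a,b))).  When trimmed
lengths differ the shorter sequence is center-gapped: its first ⌊n/2⌋
residues align from the N-terminal end, the remainder from the C-terminal
end, and each gap position costs ``gap_penalty`` (default 4).

The substitution matrix is frozen here as a literal so distances are
independent of any external matrix source.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .peptide_graph import AMINO_ACIDS

BLOSUM62 = {
    "A": {"A": 4, "C": 0, "D": -2, "E": -1, "F": -2, "G": 0, "H": -2, "I": -1, "K": -1, "L": -1, "M": -1, "N": -2, "P": -1, "Q": -1, "R": -1, "S": 1, "T": 0, "V": 0, "W": -3, "Y": -2},
    "C": {"A": 0, "C": 9, "D": -3, "E": -4, "F": -2, "G": -3, "H": -3, "I": -1, "K": -3, "L": -1, "M": -1, "N": -3, "P": -3, "Q": -3, "R": -3, "S": -1, "T": -1, "V": -1, "W": -2, "Y": -2},
    "D": {"A": -2, "C": -3, "D": 6, "E": 2, "F": -3, "G": -1, "H": -1, "I": -3, "K": -1, "L": -4, "M": -3, "N": 1, "P": -1, "Q": 0, "R": -2, "S": 0, "T": -1, "V": -3, "W": -4, "Y": -3},
    "E": {"A": -1, "C": -4, "D": 2, "E": 5, "F": -3, "G": -2, "H": 0, "I": -3, "K": 1, "L": -3, "M": -2, "N": 0, "P": -1, "Q": 2, "R": 0, "S": 0, "T": -1, "V": -2, "W": -3, "Y": -2},
    "F": {"A": -2, "C": -2, "D": -3, "E": -3, "F": 6, "G": -3, "H": -1, "I": 0, "K": -3, "L": 0, "M": 0, "N": -3, "P": -4, "Q": -3, "R": -3, "S": -2, "T": -2, "V": -1, "W": 1, "Y": 3},
    "G": {"A": 0, "C": -3, "D": -1, "E": -2, "F": -3, "G": 6, "H": -2, "I": -4, "K": -2, "L": -4, "M": -3, "N": 0, "P": -2, "Q": -2, "R": -2, "S": 0, "T": -2, "V": -3, "W": -2, "Y": -3},
    "H": {"A": -2, "C": -3, "D": -1, "E": 0, "F": -1, "G": -2, "H": 8, "I": -3, "K": -1, "L": -3, "M": -2, "N": 1, "P": -2, "Q": 0, "R": 0, "S": -1, "T": -2, "V": -3, "W": -2, "Y": 2},
    "I": {"A": -1, "C": -1, "D": -3, "E": -3, "F": 0, "G": -4, "H": -3, "I": 4, "K": -3, "L": 2, "M": 1, "N": -3, "P": -3, "Q": -3, "R": -3, "S": -2, "T": -1, "V": 3, "W": -3, "Y": -1},
    "K": {"A": -1, "C": -3, "D": -1, "E": 1, "F": -3, "G": -2, "H": -1, "I": -3, "K": 5, "L": -2, "M": -1, "N": 0, "P": -1, "Q": 1, "R": 2, "S": 0, "T": -1, "V": -2, "W": -3, "Y": -2},
    "L": {"A": -1, "C": -1, "D": -4, "E": -3, "F": 0, "G": -4, "H": -3, "I": 2, "K": -2, "L": 4, "M": 2, "N": -3, "P": -3, "Q": -2, "R": -2, "S": -2, "T": -1, "V": 1, "W": -2, "Y": -1},
    "M": {"A": -1, "C": -1, "D": -3, "E": -2, "F": 0, "G": -3, "H": -2, "I": 1, "K": -1, "L": 2, "M": 5, "N": -2, "P": -2, "Q": 0, "R": -1, "S": -1, "T": -1, "V": 1, "W": -1, "Y": -1},
    "N": {"A": -2, "C": -3, "D": 1, "E": 0, "F": -3, "G": 0, "H": 1, "I": -3, "K": 0, "L": -3, "M": -2, "N": 6, "P": -2, "Q": 0, "R": 0, "S": 1, "T": 0, "V": -3, "W": -4, "Y": -2},
    "P": {"A": -1, "C": -3, "D": -1, "E": -1, "F": -4, "G": -2, "H": -2, "I": -3, "K": -1, "L": -3, "M": -2, "N": -2, "P": 7, "Q": -1, "R": -2, "S": -1, "T": -1, "V": -2, "W": -4, "Y": -3},
    "Q": {"A": -1, "C": -3, "D": 0, "E": 2, "F": -3, "G": -2, "H": 0, "I": -3, "K": 1, "L": -2, "M": 0, "N": 0, "P": -1, "Q": 5, "R": 1, "S": 0, "T": -1, "V": -2, "W": -2, "Y": -1},
    "R": {"A": -1, "C": -3, "D": -2, "E": 0, "F": -3, "G": -2, "H": 0, "I": -3, "K": 2, "L": -2, "M": -1, "N": 0, "P": -2, "Q": 1, "R": 5, "S": -1, "T": -1, "V": -3, "W": -3, "Y": -2},
    "S": {"A": 1, "C": -1, "D": 0, "E": 0, "F": -2, "G": 0, "H": -1, "I": -2, "K": 0, "L": -2, "M": -1, "N": 1, "P": -1, "Q": 0, "R": -1, "S": 4, "T": 1, "V": -2, "W": -3, "Y": -2},
    "T": {"A": 0, "C": -1, "D": -1, "E": -1, "F": -2, "G": -2, "H": -2, "I": -1, "K": -1, "L": -1, "M": -1, "N": 0, "P": -1, "Q": -1, "R": -1, "S": 1, "T": 5, "V": 0, "W": -2, "Y": -2},
    "V": {"A": 0, "C": -1, "D": -3, "E": -2, "F": -1, "G": -3, "H": -3, "I": 3, "K": -2, "L": 1, "M": 1, "N": -3, "P": -2, "Q": -2, "R": -3, "S": -2, "T": 0, "V": 4, "W": -3, "Y": -1},
    "W": {"A": -3, "C": -2, "D": -4, "E": -3, "F": 1, "G": -2, "H": -2, "I": -3, "K": -3, "L": -2, "M": -1, "N": -4, "P": -4, "Q": -2, "R": -3, "S": -3, "T": -2, "V": -3, "W": 11, "Y": 2},
    "Y": {"A": -2, "C": -2, "D": -3, "E": -2, "F": 3, "G": -3, "H": 2, "I": -1, "K": -2, "L": -1, "M": -1, "N": -2, "P": -3, "Q": -1, "R": -2, "S": -2, "T": -2, "V": -1, "W": 2, "Y": 7},
}


@dataclass
class DistanceParams:
    gap_penalty: int = 4
    trim_n: int = 3
    trim_c: int = 2
    substitution_cap: int = 4
    weight: float = 1.0  # multiplier on the summed sequence distance

    def __post_init__(self) -> None:
        for name in ("gap_penalty", "trim_n", "trim_c", "substitution_cap"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def trim_cdr3(seq: str, params: DistanceParams | None = None) -> str:
    p = params or DistanceParams()
    if len(seq) <= p.trim_n + p.trim_c:
        raise ValueError(
            f"sequence {seq!r} too short to trim {p.trim_n}+{p.trim_c} residues")
    return seq[p.trim_n:len(seq) - p.trim_c]


def residue_distance(a: str, b: str, cap: int = 4) -> int:
    """Capped BLOSUM62 distance: max(0, min(cap, 4 − BLOSUM62(a, b)))."""
    if a not in BLOSUM62 or b not in BLOSUM62:
        raise ValueError(f"invalid residue pair ({a!r}, {b!r})")
    return max(0, min(cap, 4 - BLOSUM62[a][b]))


def _align_center_gap(short: str, long: str) -> list[tuple[str, str | None]]:
    """Pair each residue of ``long`` with one of ``short`` or a gap.

    The shorter sequence contributes its first ⌊n/2⌋ residues from the
    N-terminal end and the rest from the C-terminal end; the gap block
    lies in between (toward the N-terminal side on ties)."""
    n, m = len(short), len(long)
    lead = n // 2
    pairs: list[tuple[str, str | None]] = []
    for i in range(m):
        if i < lead:
            pairs.append((long[i], short[i]))
        elif i >= m - (n - lead):
            pairs.append((long[i], short[i - (m - n)]))
        else:
            pairs.append((long[i], None))
    return pairs


def cdr3_distance(s1: str, s2: str, params: DistanceParams | None = None) -> float:
    """Trimmed, center-gapped, BLOSUM62-capped distance between two CDR3s."""
    p = params or DistanceParams()
    t1, t2 = trim_cdr3(s1, p), trim_cdr3(s2, p)
    if len(t1) > len(t2):
        t1, t2 = t2, t1
    total = 0
    for a, b in _align_center_gap(t1, t2):
        total += p.gap_penalty if b is None else residue_distance(a, b, p.substitution_cap)
    return p.weight * total


def distance_matrix(sequences: list[str],
                    params: DistanceParams | None = None) -> DistanceMatrix:
    p = params or DistanceParams()
    n = len(sequences)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = cdr3_distance(sequences[i], sequences[j], p)
            vals[i, j] = vals[j, i] = d
    return DistanceMatrix(ids=list(sequences), values=vals)


def avg_min_distance(test_set, train_set, per_epitope: bool = True,
                     params: DistanceParams | None = None):
    """Mean over test sequences of the minimum distance to a (same-epitope)
    training sequence.

    With ``per_epitope`` the inputs are mappings epitope → sequence list and
    a per-epitope table plus the overall mean is returned; otherwise plain
    sequence lists are compared and a single number is returned."""
    p = params or DistanceParams()
    if per_epitope:
        rows = []
        all_mins: list[float] = []
        for epitope in sorted(test_set):
            if epitope not in train_set or not train_set[epitope]:
                raise ValueError(f"epitope {epitope!r} missing from training side")
            mins = [min(cdr3_distance(t, s, p) for s in train_set[epitope])
                    for t in test_set[epitope]]
            all_mins.extend(mins)
            rows.append({"epitope": epitope,
                         "avg_min_distance": float(np.mean(mins)),
                         "n_test": len(mins)})
        return pd.DataFrame(rows), float(np.mean(all_mins))
    if not test_set or not train_set:
        raise ValueError("both sets must be non-empty")
    mins = [min(cdr3_distance(t, s, p) for s in train_set) for t in test_set]
    return float(np.mean(mins))
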