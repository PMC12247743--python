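"""Synthetic epitope-specific TCR repertoires with planted motifs.

Stands in for multiplexed antigen-stimulation / database repertoires: each
simulated epitope is a random 9-mer peptide whose cognate CDR3s carry a
distinct planted k-mer (default length 3) at the center of the loop, with
a configurable fidelity (fraction of cognate CDR3s carrying the motif
intact; the remainder are pure background).  CDR3s wear the canonical
β-chain flanks ("CASS" ... "F") so that N/C-terminal trimming in the
distance module interacts with the motif the way it would on real loops.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import BindingPair
from .peptide_graph import AMINO_ACIDS


@dataclass
class SimulationConfig:
    n_epitopes: int = 4
    tcrs_per_epitope: int = 250
    cdr3_length_range: tuple[int, int] = (12, 16)
    motif_length: int = 3
    motif_fidelity: float = 0.9
    prefix: str = "CASS"
    suffix: str = "F"
    epitope_length: int = 9
    seed: int = 0
    motifs: list[str] | None = None  # override the random per-epitope motifs

    def __post_init__(self) -> None:
        if self.n_epitopes < 2:
            raise ValueError("n_epitopes must be >= 2")
        if self.tcrs_per_epitope < 1:
            raise ValueError("tcrs_per_epitope must be >= 1")
        if not 0 <= self.motif_fidelity <= 1:
            raise ValueError("motif_fidelity must lie in [0, 1]")
        lo, hi = self.cdr3_length_range
        min_len = len(self.prefix) + len(self.suffix) + self.motif_length
        if lo < min_len:
            raise ValueError(f"cdr3_length_range minimum must be >= {min_len}")
        if hi < lo:
            raise ValueError("cdr3_length_range must be (lo, hi) with hi >= lo")
        if self.motifs is not None:
            if len(self.motifs) != self.n_epitopes:
                raise ValueError("need one motif per epitope")
            if len(set(self.motifs)) != len(self.motifs):
                raise ValueError("planted motifs must be distinct across epitopes")


def _random_kmer(rng: np.random.Generator, k: int) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=k))


def simulate_repertoire(config: SimulationConfig | None = None
                        ) -> tuple[list[BindingPair], pd.DataFrame]:
    """Positive pairs plus a ground-truth table (cdr3, epitope, motif,
    has_motif).  Deterministic given ``config.seed``."""
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)

    epitopes: list[str] = []
    while len(epitopes) < cfg.n_epitopes:
        pep = _random_kmer(rng, cfg.epitope_length)
        if pep not in epitopes:
            epitopes.append(pep)
    if cfg.motifs is not None:
        motifs = list(cfg.motifs)
    else:
        motifs = []
        while len(motifs) < cfg.n_epitopes:
            m = _random_kmer(rng, cfg.motif_length)
            if m not in motifs:
                motifs.append(m)

    pairs: list[BindingPair] = []
    truth_rows = []
    pair_id = 0
    lo, hi = cfg.cdr3_length_range
    for epitope, motif in zip(epitopes, motifs):
        for _ in range(cfg.tcrs_per_epitope):
            length = int(rng.integers(lo, hi + 1))
            interior = length - len(cfg.prefix) - len(cfg.suffix)
            has_motif = bool(rng.random() < cfg.motif_fidelity)
            if has_motif:
                # motif planted at the center of the interior
                pad = interior - cfg.motif_length
                left = pad // 2
                core = (_random_kmer(rng, left) + motif
                        + _random_kmer(rng, pad - left))
            else:
                core = _random_kmer(rng, interior)
            cdr3 = cfg.prefix + core + cfg.suffix
            pairs.append(BindingPair(tcr=cdr3, epitope=epitope, label=1,
                                     origin="observed", pair_id=pair_id))
            truth_rows.append({"pair_id": pair_id, "cdr3": cdr3,
                               "epitope": epitope, "motif": motif,
                               "has_motif": has_motif})
            pair_id += 1
    return pairs, pd.DataFrame(truth_rows)


def simulate_embedding_testbed(n_points_per_label: int = 50,
                               n_labels: int = 4, separation: float = 10.0,
                               noise_sd: float = 1.0, seed: int = 0
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian blobs with centers at mutual distance >= separation.

    Isolates clustering and classifier behavior from the embedding
    trainer.  Centers sit on orthogonal axes at separation/sqrt(2) * e_i,
    so every pair of centers is exactly ``separation`` apart (Euclidean).
    """
    if separation <= 0:
        raise ValueError("separation must be > 0")
    rng = np.random.default_rng(seed)
    dim = n_labels
    centers = np.eye(n_labels, dim) * (separation / np.sqrt(2))
    X = np.vstack([
        centers[i] + noise_sd * rng.standard_normal((n_points_per_label, dim))
        for i in range(n_labels)])
    labels = np.repeat(np.arange(n_labels), n_points_per_label)
    return X, labels
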