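"""Empirical amino-acid substitution models (LG, VT) and a 3-state toy model.

A model is a general time-reversible rate matrix Q = S·diag(pi), normalised
so the expected substitution rate at equilibrium is one
(-sum_i pi_i Q_ii = 1), with transition probabilities P(t) = exp(Qt)
computed by symmetric eigendecomposition. LG and VT exchangeabilities and
their published equilibrium frequencies are bundled as data files.
"""
from __future__ import annotations

from importlib import resources
from typing import Optional, Sequence, Union

import numpy as np

#: residue order used by the bundled exchangeability files
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
#: 3-letter alphabet of the exhaustively testable toy model
TOY3_ALPHABET = "ACD"

_TOY3_EXCHANGE = np.array([[0.0, 1.0, 2.0],
                           [1.0, 0.0, 0.5],
                           [2.0, 0.5, 0.0]])
_TOY3_FREQS = np.array([0.5, 0.3, 0.2])


def _load_bundled(name: str):
    text = resources.files("get3atlas.data").joinpath(name).read_text()
    rows, freqs = [], None
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("F "):
            freqs = np.array([float(x) for x in line.split()[1:]])
        else:
            rows.append([float(x) for x in line.split()])
    k = len(rows) + 1
    S = np.zeros((k, k))
    for i, row in enumerate(rows, start=1):
        S[i, :i] = row
    S = S + S.T
    return S, freqs


class SubstitutionModel:
    """Reversible substitution model over a finite residue alphabet."""

    def __init__(self, name: str, alphabet: str, exchangeabilities: np.ndarray,
                 frequencies: np.ndarray):
        self.name = name
        self.alphabet = alphabet
        self.k = len(alphabet)
        S = np.asarray(exchangeabilities, dtype=float)
        pi = np.asarray(frequencies, dtype=float)
        if S.shape != (self.k, self.k):
            raise ValueError("exchangeability matrix shape mismatch")
        if not np.allclose(S, S.T):
            raise ValueError("exchangeabilities must be symmetric")
        if pi.shape != (self.k,) or np.any(pi <= 0):
            raise ValueError("frequencies must be positive")
        pi = pi / pi.sum()
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        scale = -np.dot(pi, np.diag(Q))
        Q = Q / scale
        self.S = S
        self.freqs = pi
        self.Q = Q
        # symmetrised eigendecomposition: B = D^1/2 Q D^-1/2 is symmetric
        sq = np.sqrt(pi)
        B = (Q * sq[:, None]) / sq[None, :]
        w, U = np.linalg.eigh((B + B.T) / 2.0)
        self._eigvals = w
        self._left = U.T * sq[None, :]          # U^T D^1/2
        self._right = (U / sq[:, None])         # D^-1/2 U
        self._index = {c: i for i, c in enumerate(alphabet)}

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to one."""
        if t < 0:
            raise ValueError("branch length must be >= 0")
        P = (self._right * np.exp(self._eigvals * t)[None, :]) @ self._left
        return np.clip(P, 0.0, None)

    def transition_matrices(self, ts: np.ndarray) -> np.ndarray:
        """Stack of P(t) for a vector of times, shape (len(ts), k, k)."""
        ts = np.asarray(ts, dtype=float)
        E = np.exp(np.outer(ts, self._eigvals))           # (m, k)
        P = np.einsum("ik,mk,kj->mij", self._right, E, self._left)
        return np.clip(P, 0.0, None)

    def encode(self, residues: str) -> np.ndarray:
        """Indices into the alphabet; gaps/unknowns become -1 (missing)."""
        return np.array([self._index.get(c, -1) for c in residues], dtype=np.int64)

    def with_frequencies(self, frequencies: np.ndarray) -> "SubstitutionModel":
        return SubstitutionModel(self.name, self.alphabet, self.S, frequencies)

    def __repr__(self) -> str:  # pragma: no cover
        return f"SubstitutionModel({self.name}, k={self.k})"


def load_model(name: str,
               frequencies: Union[str, Sequence[float]] = "model",
               alignment: Optional[object] = None) -> SubstitutionModel:
    """Load LG, VT or TOY3.

    ``frequencies`` is ``"model"`` (the published frequencies),
    ``"empirical"`` (counted from ``alignment``), or an explicit vector.
    """
    name = name.upper()
    if name == "TOY3":
        model = SubstitutionModel("TOY3", TOY3_ALPHABET, _TOY3_EXCHANGE, _TOY3_FREQS)
    elif name in ("LG", "VT"):
        S, bf = _load_bundled(f"{name.lower()}_model.txt")
        model = SubstitutionModel(name, AA_ORDER, S, bf)
    else:
        raise ValueError(f"unknown model {name!r}")
    if isinstance(frequencies, str):
        if frequencies == "model":
            return model
        if frequencies == "empirical":
            if alignment is None:
                raise ValueError("empirical frequencies require an alignment")
            return model.with_frequencies(empirical_frequencies(alignment, model.alphabet))
        raise ValueError(f"unknown frequency mode {frequencies!r}")
    return model.with_frequencies(np.asarray(frequencies, dtype=float))


def empirical_frequencies(alignment, alphabet: str = AA_ORDER,
                          pseudocount: float = 0.5) -> np.ndarray:
    """Residue frequencies counted from an AlignmentBlock (gaps ignored)."""
    counts = np.full(len(alphabet), pseudocount)
    index = {c: i for i, c in enumerate(alphabet)}
    for _, row in alignment.rows:
        for c in row:
            i = index.get(c)
            if i is not None:
                counts[i] += 1
    return counts / counts.sum()
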