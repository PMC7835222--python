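"""Per-column residue conservation by Jensen-Shannon divergence.

Each alignment column's (sequence-weighted, pseudocounted) amino-acid
distribution is compared against the background distribution of residues
under no evolutionary pressure — the marginal amino-acid frequencies
underlying the BLOSUM62 substitution matrix. The base-2 JSD is bounded in
[0, 1]; high values flag evolutionarily constrained positions. The raw
column score is penalised linearly by the (weighted) gap fraction, and a
windowed score blends each column with the mean of its neighbours so that
locally clustered constraint is rewarded.

Sequence weighting is position-based: per column c with ``r_c`` distinct
symbols (gap included) of which sequence i's symbol occurs ``s_ci`` times,
the raw weight of sequence i is the mean over columns of ``1/(r_c * s_ci)``,
normalised to sum to one. Over-sampled near-identical sequences are thereby
down-weighted; "surprising" sequences carrying rare residues gain weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AA_ALPHABET, GAP, MultipleAlignment

N_AA = 20
_GAP_CODE = 20  # gaps and (lenient-mode) ambiguity codes: excluded from counts

# Published marginal amino-acid frequencies underlying BLOSUM62, indexed in
# ACDEFGHIKLMNPQRSTVWY order. Leucine is the most frequent residue (0.099).
_BLOSUM62_BG = {
    "A": 0.074, "C": 0.025, "D": 0.054, "E": 0.054, "F": 0.047,
    "G": 0.074, "H": 0.026, "I": 0.068, "K": 0.058, "L": 0.099,
    "M": 0.025, "N": 0.045, "P": 0.039, "Q": 0.034, "R": 0.052,
    "S": 0.057, "T": 0.051, "V": 0.073, "W": 0.013, "Y": 0.032,
}

_ENCODER = np.full(128, _GAP_CODE, dtype=np.uint8)
for _i, _aa in enumerate(AA_ALPHABET):
    _ENCODER[ord(_aa)] = _i


def blosum62_background() -> np.ndarray:
    """The 20 BLOSUM62 background frequencies (ACDEFGHIKLMNPQRSTVWY order)."""
    bg = np.array([_BLOSUM62_BG[a] for a in AA_ALPHABET], dtype=float)
    return bg / bg.sum()


@dataclass
class ConservationParams:
    """Scoring parameters.

    window_radius
        Columns on each side blended into the windowed score (default 3).
    window_weight
        Weight of the neighbourhood mean in the blend, in [0, 1].
    pseudocount
        Added to each residue's weighted count to keep distributions strictly
        positive.
    use_sequence_weighting
        Position-based weighting on/off (equal weights when off).
    """

    window_radius: int = 3
    window_weight: float = 0.5
    pseudocount: float = 1e-7
    use_sequence_weighting: bool = True
    gap_penalty_mode: str = "linear"

    def __post_init__(self) -> None:
        if self.window_radius < 0:
            raise ValueError("window_radius must be >= 0")
        if not 0.0 <= self.window_weight <= 1.0:
            raise ValueError("window_weight must lie in [0, 1]")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if self.gap_penalty_mode != "linear":
            raise ValueError("only linear gap penalty is supported")


@dataclass
class ConservationProfile:
    """Raw and windowed per-column scores plus the reference-residue map."""

    raw: np.ndarray          # S_c, one per column
    windowed: np.ndarray     # S'_c
    gap_fraction: np.ndarray
    reference_id: str
    # reference_map[r] = 0-based column of reference residue r+1
    reference_map: np.ndarray
    params: ConservationParams = field(default_factory=ConservationParams)

    @property
    def n_columns(self) -> int:
        return self.raw.size

    @property
    def reference_length(self) -> int:
        return self.reference_map.size

    def residue_scores(self, residues: np.ndarray | list[int]) -> np.ndarray:
        """Windowed scores at the given 1-based reference residue numbers."""
        idx = np.asarray(residues, dtype=int) - 1
        if (idx < 0).any() or (idx >= self.reference_length).any():
            raise ValueError("residue number outside the reference sequence")
        return self.windowed[self.reference_map[idx]]

    def to_frame(self) -> pd.DataFrame:
        ref_res = np.full(self.n_columns, 0, dtype=int)
        ref_res[self.reference_map] = np.arange(1, self.reference_length + 1)
        return pd.DataFrame(
            {
                "column": np.arange(1, self.n_columns + 1),
                "ref_residue": np.where(ref_res > 0, ref_res, np.nan),
                "gap_fraction": self.gap_fraction,
                "raw": self.raw,
                "windowed": self.windowed,
            }
        )


def encode_alignment(aln: MultipleAlignment) -> np.ndarray:
    """Integer matrix (n_sequences x n_columns); 0-19 residues, 20 gap."""
    rows = [np.frombuffer(s.encode("ascii"), dtype=np.uint8) for s in aln.sequences]
    return _ENCODER[np.vstack(rows)]


def sequence_weights(aln: MultipleAlignment | np.ndarray) -> np.ndarray:
    """Position-based sequence weights, normalised to sum to one."""
    mat = aln if isinstance(aln, np.ndarray) else encode_alignment(aln)
    return _weights_from_matrix(mat)


def _weights_from_matrix(mat: np.ndarray) -> np.ndarray:
    n, ncol = mat.shape
    counts = np.zeros((ncol, N_AA + 1), dtype=float)
    cols = np.tile(np.arange(ncol), n)
    np.add.at(counts, (cols, mat.ravel()), 1.0)
    r = (counts > 0).sum(axis=1).astype(float)          # distinct symbols per column
    s = counts[np.arange(ncol)[None, :], mat]           # copies of own symbol (n, ncol)
    raw = (1.0 / (r[None, :] * s)).mean(axis=1)
    return raw / raw.sum()


def _distributions(
    mat: np.ndarray,
    weights: np.ndarray,
    pseudocount: float,
    columns: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted residue distributions and gap fractions for the given columns."""
    sub = mat if columns is None else mat[:, columns]
    n, k = sub.shape
    wcounts = np.zeros((k, N_AA + 1), dtype=float)
    cols = np.tile(np.arange(k), n)
    np.add.at(wcounts, (cols, sub.ravel()), np.repeat(weights, k))
    gap_fraction = wcounts[:, _GAP_CODE] / weights.sum()
    residue_mass = wcounts[:, :N_AA]
    denom = residue_mass.sum(axis=1, keepdims=True) + N_AA * pseudocount
    p = (residue_mass + pseudocount) / denom
    all_gap = residue_mass.sum(axis=1) == 0
    p[all_gap] = 1.0 / N_AA  # uniform placeholder; scored 0 via gap penalty
    return p, gap_fraction


def column_distribution(
    aln: MultipleAlignment,
    column: int,
    weights: np.ndarray | None = None,
    pseudocount: float = 1e-7,
) -> tuple[np.ndarray, float]:
    """Weighted amino-acid distribution and gap fraction of one column (0-based)."""
    mat = encode_alignment(aln)
    if not 0 <= column < mat.shape[1]:
        raise ValueError(f"column {column} outside alignment of {mat.shape[1]} columns")
    if weights is None:
        weights = np.full(mat.shape[0], 1.0 / mat.shape[0])
    p, gaps = _distributions(mat, np.asarray(weights, dtype=float), pseudocount, np.array([column]))
    return p[0], float(gaps[0])


def jsd(p, q) -> float:
    """Base-2 Jensen-Shannon divergence between two distributions; in [0, 1]."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("distributions must share a support")
    for name, d in (("p", p), ("q", q)):
        if abs(d.sum() - 1.0) > 1e-6 or (d < 0).any():
            raise ValueError(f"{name} is not a normalised distribution")
    return float(_jsd_rows(p[None, :], q)[0])


def _jsd_rows(P: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Row-wise base-2 JSD of each row of P against q."""
    m = 0.5 * (P + q[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(P > 0, P * (np.log2(np.maximum(P, 1e-300)) - np.log2(m)), 0.0)
        t2 = np.where(q[None, :] > 0, q[None, :] * (np.log2(np.maximum(q[None, :], 1e-300)) - np.log2(m)), 0.0)
    val = 0.5 * t1.sum(axis=1) + 0.5 * t2.sum(axis=1)
    return np.clip(val, 0.0, 1.0)


def column_score(
    aln: MultipleAlignment,
    column: int,
    weights: np.ndarray | None = None,
    background: np.ndarray | None = None,
    pseudocount: float = 1e-7,
) -> float:
    """Raw conservation score of one column: JSD vs background x (1 - gap fraction)."""
    if background is None:
        background = blosum62_background()
    p, gap_fraction = column_distribution(aln, column, weights, pseudocount)
    return float(_jsd_rows(p[None, :], background)[0] * (1.0 - gap_fraction))


def _window_smooth(raw: np.ndarray, radius: int, lam: float) -> np.ndarray:
    if radius == 0 or lam == 0.0:
        return raw.copy()
    ncol = raw.size
    csum = np.concatenate([[0.0], np.cumsum(raw)])
    out = np.empty_like(raw)
    idx = np.arange(ncol)
    lo = np.maximum(idx - radius, 0)
    hi = np.minimum(idx + radius, ncol - 1)
    totals = csum[hi + 1] - csum[lo] - raw
    counts = (hi - lo).astype(float)  # window size minus the column itself
    with np.errstate(invalid="ignore", divide="ignore"):
        neigh_mean = np.where(counts > 0, totals / np.maximum(counts, 1.0), raw)
    out = (1.0 - lam) * raw + lam * neigh_mean
    return out


def _profile_from_matrix(
    mat: np.ndarray,
    params: ConservationParams,
    background: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(raw, windowed, gap_fraction) for an encoded alignment matrix."""
    n = mat.shape[0]
    if params.use_sequence_weighting:
        weights = _weights_from_matrix(mat)
    else:
        weights = np.full(n, 1.0 / n)
    P, gap_fraction = _distributions(mat, weights, params.pseudocount)
    raw = _jsd_rows(P, background) * (1.0 - gap_fraction)
    windowed = _window_smooth(raw, params.window_radius, params.window_weight)
    return raw, windowed, gap_fraction


def conservation_profile(
    aln: MultipleAlignment,
    reference_id: str,
    params: ConservationParams | None = None,
    background: np.ndarray | None = None,
) -> ConservationProfile:
    """Score every column of the alignment and map columns to reference residues."""
    if params is None:
        params = ConservationParams()
    if background is None:
        background = blosum62_background()
    if reference_id not in aln.ids:
        raise KeyError(f"reference id {reference_id!r} not in alignment")
    mat = encode_alignment(aln)
    raw, windowed, gap_fraction = _profile_from_matrix(mat, params, background)
    ref_row = aln.row(reference_id)
    reference_map = np.flatnonzero(
        np.frombuffer(ref_row.encode("ascii"), dtype=np.uint8) != ord(GAP)
    )
    return ConservationProfile(
        raw=raw,
        windowed=windowed,
        gap_fraction=gap_fraction,
        reference_id=reference_id,
        reference_map=reference_map,
        params=params,
    )
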