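"""Partner presence/absence-conditioned conservation comparison.

Two ortholog alignments — one from organisms that also possess the
interaction partner, one from organisms where the partner is absent — are
scored with the same conservation parameters, and the mean difference in
windowed score over a region of interest (in reference-residue coordinates)
is the coevolution statistic: positive means the region is more conserved
where the partner exists.

Uncertainty comes from two complementary tests:

* a label-permutation test — organism rows are pooled and reassigned to the
  two sets (sizes preserved), profiles and the region delta recomputed per
  permutation; the reference sequence acts as the coordinate anchor, is
  present in both alignments, and stays fixed;
* a Wilcoxon signed-rank test on the per-residue score deltas.

The permutation test requires both alignments to share one column space
(equal column counts), which holds for the simulated families and for any
pair of profiles cut from a single joint alignment.

The default region of interest is residues 336-501 of human ALDH1A1 — the
C-terminal region that binds PRMT3; residues 371-501 (the two-hybrid clone
boundary) is offered as a named preset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .conservation import (
    ConservationParams,
    ConservationProfile,
    _distributions,
    _jsd_rows,
    _weights_from_matrix,
    blosum62_background,
    conservation_profile,
    encode_alignment,
)
from .io import MultipleAlignment
from .stats import TestResult, wilcoxon_signed_rank

REGION_PRESETS = {
    "al_ctr": (336, 501),   # C-terminal region construct
    "y2h_clone": (371, 501),  # two-hybrid clone boundary
}


@dataclass
class RegionComparison:
    region: tuple[int, int]
    paired: pd.DataFrame  # residue, score_pos, score_neg, delta
    delta_mean: float
    permutation_p: float
    signed_rank_p: float
    n_permutations: int
    seed: int
    n_excluded: int = 0


def region_scores(
    profile_pos: ConservationProfile,
    profile_neg: ConservationProfile,
    region: tuple[int, int],
) -> pd.DataFrame:
    """Paired per-residue windowed scores over a 1-based inclusive region."""
    start, end = region
    if start < 1 or end < start:
        raise ValueError(f"invalid region {region}")
    residues = np.arange(start, end + 1)
    max_mapped = min(profile_pos.reference_length, profile_neg.reference_length)
    keep = residues <= max_mapped
    n_excluded = int((~keep).sum())
    residues = residues[keep]
    if residues.size == 0:
        raise ValueError("no comparable residues: region not mapped in both profiles")
    score_pos = profile_pos.residue_scores(residues)
    score_neg = profile_neg.residue_scores(residues)
    df = pd.DataFrame(
        {
            "residue": residues,
            "score_pos": score_pos,
            "score_neg": score_neg,
            "delta": score_pos - score_neg,
        }
    )
    df.attrs["n_excluded"] = n_excluded
    return df


def delta_statistic(paired: pd.DataFrame) -> float:
    """Mean per-residue score difference (positive = partner-positive more conserved)."""
    return float(paired["delta"].mean())


def _region_delta(
    mat_pos: np.ndarray,
    mat_neg: np.ndarray,
    region_cols: np.ndarray,
    params: ConservationParams,
    background: np.ndarray,
) -> float:
    """Mean windowed-score delta over the given columns, computed only on the
    column range the window needs (identical to the full-profile scores)."""
    radius = params.window_radius
    ncol = mat_pos.shape[1]
    lo = max(int(region_cols.min()) - radius, 0)
    hi = min(int(region_cols.max()) + radius, ncol - 1)
    span = np.arange(lo, hi + 1)
    deltas = []
    for mat in (mat_pos, mat_neg):
        if params.use_sequence_weighting:
            weights = _weights_from_matrix(mat)
        else:
            weights = np.full(mat.shape[0], 1.0 / mat.shape[0])
        P, gapfrac = _distributions(mat, weights, params.pseudocount, span)
        raw_span = _jsd_rows(P, background) * (1.0 - gapfrac)
        # emulate full-length window truncation: span already clipped to edges
        windowed_span = _window_smooth_span(raw_span, span, ncol, radius, params.window_weight)
        deltas.append(windowed_span[np.searchsorted(span, region_cols)])
    return float(np.mean(deltas[0] - deltas[1]))


def _window_smooth_span(
    raw_span: np.ndarray, span: np.ndarray, ncol: int, radius: int, lam: float
) -> np.ndarray:
    """Window smoothing of a contiguous span, truncating at alignment edges.

    ``span`` must already include ``radius`` columns of context on each side
    wherever the alignment extends that far, so results match the
    full-profile computation exactly.
    """
    if radius == 0 or lam == 0.0:
        return raw_span.copy()
    k = raw_span.size
    csum = np.concatenate([[0.0], np.cumsum(raw_span)])
    idx = np.arange(k)
    glo = np.maximum(span - radius, 0)
    ghi = np.minimum(span + radius, ncol - 1)
    # clamp to the span; windows of the context columns themselves are
    # truncated here, but only the region columns' windows (fully contained
    # by construction) are ever consumed
    lo = np.searchsorted(span, glo, side="left")
    hi = np.searchsorted(span, ghi, side="right") - 1
    totals = csum[hi + 1] - csum[lo] - raw_span
    counts = (hi - lo).astype(float)
    neigh_mean = np.where(counts > 0, totals / np.maximum(counts, 1.0), raw_span)
    return (1.0 - lam) * raw_span + lam * neigh_mean


def permutation_test(
    aln_pos: MultipleAlignment,
    aln_neg: MultipleAlignment,
    reference_id: str,
    region: tuple[int, int],
    params: ConservationParams | None = None,
    n_permutations: int = 999,
    seed: int | None = None,
) -> tuple[float, float, np.ndarray]:
    """Two-sided label-permutation test of the region delta statistic.

    Returns (p_value, observed_delta, permuted_deltas). The reference row is
    required in both alignments (coordinate anchor) and is never permuted;
    organism rows are pooled and reassigned preserving set sizes. p uses the
    add-one estimator (1 + #{|delta*| >= |delta_obs|}) / (N + 1), so the
    smallest attainable p is 1/(N+1).
    """
    if n_permutations < 19:
        raise ValueError("need at least 19 permutations for a usable p-value floor")
    if params is None:
        params = ConservationParams()
    if aln_pos.n_columns != aln_neg.n_columns:
        raise ValueError("permutation test requires alignments over one column space")
    if reference_id not in aln_pos.ids or reference_id not in aln_neg.ids:
        raise ValueError(f"reference id {reference_id!r} must be present in both alignments")
    background = blosum62_background()

    prof_pos = conservation_profile(aln_pos, reference_id, params, background)
    prof_neg = conservation_profile(aln_neg, reference_id, params, background)
    paired = region_scores(prof_pos, prof_neg, region)
    observed = delta_statistic(paired)
    region_cols = prof_pos.reference_map[paired["residue"].to_numpy() - 1]

    mat_pos = encode_alignment(aln_pos)
    mat_neg = encode_alignment(aln_neg)
    ref_pos = aln_pos.ids.index(reference_id)
    ref_neg = aln_neg.ids.index(reference_id)
    ref_row = mat_pos[ref_pos]
    org_pool = np.vstack(
        [np.delete(mat_pos, ref_pos, axis=0), np.delete(mat_neg, ref_neg, axis=0)]
    )
    n_pos = mat_pos.shape[0] - 1
    if n_pos < 2 or org_pool.shape[0] - n_pos < 2:
        raise ValueError("both sets need >= 2 organism sequences")

    rng = np.random.default_rng(seed)
    deltas = np.empty(n_permutations)
    for b in range(n_permutations):
        perm = rng.permutation(org_pool.shape[0])
        pos_mat = np.vstack([ref_row[None, :], org_pool[perm[:n_pos]]])
        neg_mat = np.vstack([ref_row[None, :], org_pool[perm[n_pos:]]])
        deltas[b] = _region_delta(pos_mat, neg_mat, region_cols, params, background)
    n_extreme = int((np.abs(deltas) >= abs(observed) - 1e-12).sum())
    p = (1 + n_extreme) / (n_permutations + 1)
    return p, observed, deltas


def signed_rank_test(paired: pd.DataFrame) -> TestResult:
    """Paired Wilcoxon signed-rank test on the per-residue deltas."""
    return wilcoxon_signed_rank(paired["delta"].to_numpy())


def compare_regions(
    aln_pos: MultipleAlignment,
    aln_neg: MultipleAlignment,
    reference_id: str,
    region: tuple[int, int] = REGION_PRESETS["al_ctr"],
    params: ConservationParams | None = None,
    n_permutations: int = 999,
    seed: int = 0,
) -> RegionComparison:
    """Full region comparison: paired scores, delta, and both tests."""
    if params is None:
        params = ConservationParams()
    prof_pos = conservation_profile(aln_pos, reference_id, params)
    prof_neg = conservation_profile(aln_neg, reference_id, params)
    paired = region_scores(prof_pos, prof_neg, region)
    perm_p, observed, _ = permutation_test(
        aln_pos, aln_neg, reference_id, region, params, n_permutations, seed
    )
    sr = signed_rank_test(paired)
    return RegionComparison(
        region=region,
        paired=paired,
        delta_mean=observed,
        permutation_p=perm_p,
        signed_rank_p=sr.p_value,
        n_permutations=n_permutations,
        seed=seed,
        n_excluded=paired.attrs.get("n_excluded", 0),
    )
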