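"""Synthetic data with planted ground truth for every pipeline stage.

Three generators emulate the statistical structure the analyses assume:

* ortholog families with a planted high-conservation interface region in
  partner-positive organisms, strain duplicates sharing a species key, and a
  diverged human paralog decoy;
* differential-expression tables for two regulator-defined conditions with
  planted target medians and up/down directionality;
* linear NADH-accumulation time courses with optional fractional inhibition
  and Gaussian noise.

Each generator takes an explicit seed, draws from a single
``numpy.random.default_rng`` stream, and returns a truth report sufficient
to score the downstream stage without re-reading the config.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io import AA_ALPHABET, SequenceRecord, TargetList, TimeCourse

CONDITION_A = "AL1HighPR3Low"
CONDITION_B = "AL1HighPR3High"


# ---------------------------------------------------------------------------
# ortholog families


@dataclass
class MsaSimConfig:
    """Planted ortholog-family simulation.

    Every organism sequence derives from one random reference by independent
    per-site substitution; sites inside ``region`` (1-based inclusive) use
    ``p_sub_region_pos`` in partner-positive organisms and
    ``p_sub_region_neg`` in partner-negative ones, all other sites use
    ``p_sub_background``. Substituted residues are uniform over the 19
    alternatives, so columnwise expectations have closed forms. No indels:
    alignments are trivially columnwise.
    """

    reference_length: int = 200
    n_partner_pos: int = 30
    n_partner_neg: int = 30
    region: tuple[int, int] = (101, 130)
    p_sub_background: float = 0.3
    p_sub_region_pos: float = 0.02
    p_sub_region_neg: float = 0.3
    n_strain_duplicates: int = 4
    paralog_divergence: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.region
        if not (1 <= lo <= hi <= self.reference_length):
            raise ValueError(f"region {self.region} outside [1, {self.reference_length}]")
        for name in ("p_sub_background", "p_sub_region_pos", "p_sub_region_neg", "paralog_divergence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if min(self.n_partner_pos, self.n_partner_neg, self.n_strain_duplicates) < 0:
            raise ValueError("counts must be >= 0")


@dataclass
class FamilySim:
    reference: SequenceRecord
    paralog: SequenceRecord
    partner_positive: list[SequenceRecord]
    partner_negative: list[SequenceRecord]
    truth: pd.DataFrame  # id, organism, species_key, set, is_strain_duplicate
    config: MsaSimConfig


def _mutate(ref: np.ndarray, p_site: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Per-site substitution of an encoded sequence, uniform over alternatives."""
    hit = rng.random(ref.size) < p_site
    shift = 1 + rng.integers(0, 19, size=ref.size)
    return np.where(hit, (ref + shift) % 20, ref)


def _decode(codes: np.ndarray) -> str:
    return "".join(AA_ALPHABET[c] for c in codes)


def simulate_ortholog_families(cfg: MsaSimConfig) -> FamilySim:
    rng = np.random.default_rng(cfg.seed)
    L = cfg.reference_length
    ref_codes = rng.integers(0, 20, size=L)
    lo, hi = cfg.region
    region_mask = np.zeros(L, dtype=bool)
    region_mask[lo - 1 : hi] = True

    p_pos = np.where(region_mask, cfg.p_sub_region_pos, cfg.p_sub_background)
    p_neg = np.where(region_mask, cfg.p_sub_region_neg, cfg.p_sub_background)

    reference = SequenceRecord(id="ALDH1A1_HUMAN", organism="Homo sapiens", sequence=_decode(ref_codes))
    par_codes = _mutate(ref_codes, np.full(L, cfg.paralog_divergence), rng)
    paralog = SequenceRecord(id="PARALOG_HUMAN", organism="Homo sapiens", sequence=_decode(par_codes))

    rows = []
    pos: list[SequenceRecord] = []
    neg: list[SequenceRecord] = []
    for i in range(cfg.n_partner_pos):
        organism = f"Posgenus{i:03d} simulans"
        rec = SequenceRecord(
            id=f"POS{i:03d}", organism=organism, sequence=_decode(_mutate(ref_codes, p_pos, rng))
        )
        pos.append(rec)
        rows.append((rec.id, organism, rec.species_key, "partner_positive", False))
    for i in range(cfg.n_partner_neg):
        organism = f"Neggenus{i:03d} simulans"
        rec = SequenceRecord(
            id=f"NEG{i:03d}", organism=organism, sequence=_decode(_mutate(ref_codes, p_neg, rng))
        )
        neg.append(rec)
        rows.append((rec.id, organism, rec.species_key, "partner_negative", False))

    hosts = list(pos) + list(neg)
    if cfg.n_strain_duplicates > 0 and hosts:
        picks = rng.choice(len(hosts), size=min(cfg.n_strain_duplicates, len(hosts)), replace=False)
        for k, host_idx in enumerate(sorted(int(x) for x in picks)):
            host = hosts[host_idx]
            in_pos = host_idx < len(pos)
            p_site = p_pos if in_pos else p_neg
            rec = SequenceRecord(
                id=f"{host.id}S{k + 1}",
                organism=f"{host.organism} strain {k + 1}",
                sequence=_decode(_mutate(ref_codes, p_site, rng)),
            )
            (pos if in_pos else neg).append(rec)
            rows.append(
                (rec.id, rec.organism, rec.species_key,
                 "partner_positive" if in_pos else "partner_negative", True)
            )

    truth = pd.DataFrame(
        rows, columns=["id", "organism", "species_key", "set", "is_strain_duplicate"]
    )
    return FamilySim(
        reference=reference,
        paralog=paralog,
        partner_positive=pos,
        partner_negative=neg,
        truth=truth,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# differential-expression tables


@dataclass
class DeSimConfig:
    """Two-condition DE tables with planted target medians and directionality.

    Shared targets move with median ``mu_pos`` in condition A and ``mu_neg``
    in condition B. When directionality fractions are given (the default), a
    fixed count ``round(p*n)`` of targets is concordant (fold change of the
    condition's expected sign, folded normal located so the planted mixture
    median equals mu) and the rest are discordant with small wrong-sign fold
    changes (half-normal, ``discordant_scale``) — mirroring real DE tables
    where wrong-direction targets respond weakly. With
    ``p_up_pos=p_down_neg=None`` targets are plain Normal(mu, sigma) draws.
    Background genes are Normal(0, sigma) everywhere; regulator genes are set
    exactly per ``regulator_spec``.
    """

    n_targets_shared: int = 33
    n_background_genes: int = 300
    mu_pos: float = 2.5
    mu_neg: float = -2.6
    sigma: float = 1.5
    p_up_pos: float | None = 0.70
    p_down_neg: float | None = 0.73
    discordant_scale: float = 0.4
    n_targets_down: int = 5
    regulator_spec: dict[str, list[tuple[str, float, bool]]] = field(
        default_factory=lambda: {
            CONDITION_A: [("ALDH1A1", 3.8, True), ("PRMT3", -1.2, True)],
            CONDITION_B: [("ALDH1A1", 1.4, True), ("PRMT3", 1.1, True)],
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if min(self.n_targets_shared, self.n_background_genes, self.n_targets_down) < 0:
            raise ValueError("counts must be >= 0")
        for p in (self.p_up_pos, self.p_down_neg):
            if p is not None and not 0.5 < p <= 1.0:
                raise ValueError("directionality fractions must lie in (0.5, 1]")


@dataclass
class DeSim:
    table_a: pd.DataFrame  # gene, log2fc, significant
    table_b: pd.DataFrame
    targets: TargetList
    truth: dict
    config: DeSimConfig


def _directional_draws(
    n: int, mu: float, sigma: float, p_conc: float | None, disc_scale: float,
    sign: float, rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """Fold changes for one condition's targets; returns (values, n_concordant)."""
    if p_conc is None:
        return sign * rng.normal(mu, sigma, size=n), n
    k = int(round(p_conc * n))
    mag = abs(mu)
    if k < n:
        # place the concordant component so the planted mixture median is mu:
        # (n/2 - (n-k)) / k of the concordant mass lies below |mu|
        frac = (0.5 * n - (n - k)) / k
        loc = mag - sigma * norm.ppf(frac)
    else:
        loc = mag
    conc = np.abs(rng.normal(loc, sigma, size=k))
    disc = -np.abs(rng.normal(0.0, disc_scale, size=n - k))
    vals = sign * np.concatenate([conc, disc])
    return vals[rng.permutation(n)], k


def simulate_de_tables(cfg: DeSimConfig) -> DeSim:
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_targets_shared
    target_genes = [f"RATGT{i:03d}" for i in range(n)]
    down_genes = [f"RADWN{i:03d}" for i in range(cfg.n_targets_down)]
    background = [f"BGGN{i:04d}" for i in range(cfg.n_background_genes)]

    vals_a, k_a = _directional_draws(
        n, cfg.mu_pos, cfg.sigma, cfg.p_up_pos, cfg.discordant_scale, +1.0, rng
    )
    vals_b, k_b = _directional_draws(
        n, abs(cfg.mu_neg), cfg.sigma, cfg.p_down_neg, cfg.discordant_scale, -1.0, rng
    )

    def build(cond: str, target_vals: np.ndarray) -> pd.DataFrame:
        genes, fcs, sig = [], [], []
        for (g, fc, s) in cfg.regulator_spec.get(cond, []):
            genes.append(g)
            fcs.append(fc)
            sig.append(bool(s))
        genes += target_genes
        fcs += list(target_vals)
        sig += [True] * n
        down_vals = rng.normal(0.0, cfg.sigma, size=cfg.n_targets_down)
        genes += down_genes
        fcs += list(down_vals)
        sig += [True] * cfg.n_targets_down
        bg_vals = rng.normal(0.0, cfg.sigma, size=cfg.n_background_genes)
        genes += background
        fcs += list(bg_vals)
        sig += [False] * cfg.n_background_genes
        return pd.DataFrame({"gene": genes, "log2fc": fcs, "significant": sig})

    table_a = build(CONDITION_A, vals_a)
    table_b = build(CONDITION_B, vals_b)
    targets = TargetList(
        frame=pd.DataFrame(
            {
                "gene": target_genes + down_genes,
                "expected_direction": ["up"] * n + ["down"] * cfg.n_targets_down,
            }
        )
    )
    truth = {
        "target_genes": target_genes,
        "planted_median_a": cfg.mu_pos,
        "planted_median_b": cfg.mu_neg,
        "n_up_a": k_a if cfg.p_up_pos is not None else int((vals_a > 0).sum()),
        "n_down_b": k_b if cfg.p_down_neg is not None else int((vals_b < 0).sum()),
        "n_targets": n,
        "values_a": vals_a,
        "values_b": vals_b,
    }
    return DeSim(table_a=table_a, table_b=table_b, targets=targets, truth=truth, config=cfg)


# ---------------------------------------------------------------------------
# kinetic time courses

NADH_EXTINCTION_AU_PER_UM = 0.00622  # 6.22 mM^-1 cm^-1 at 340 nm, 1 cm path


@dataclass
class KineticsSimConfig:
    """Linear product-accumulation time courses with fractional inhibition.

    concentration(t) = v_true * (1 - inhibition_fraction) * t + N(0, noise_sd)
    sampled every ``interval`` minutes for ``duration`` minutes (0 included),
    matching a plate-reader kinetic read every 2 min for 60 min.
    """

    v_true: float = 1.0  # µM/min uninhibited rate
    noise_sd: float = 0.2  # µM
    duration: float = 60.0  # min
    interval: float = 2.0  # min
    conditions: dict[str, float] = field(
        default_factory=lambda: {"control": 0.0, "PRMT3_FL": 0.3}
    )
    n_replicates: int = 3
    as_absorbance: bool = False
    standard_curve_slope: float = NADH_EXTINCTION_AU_PER_UM
    seed: int = 0

    def __post_init__(self) -> None:
        if self.interval <= 0:
            raise ValueError("interval must be > 0")
        if self.duration < 3 * self.interval:
            raise ValueError("duration must cover >= 3 sampling intervals")
        for cond, f in self.conditions.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"inhibition_fraction for {cond!r} outside [0, 1]")


def simulate_timecourses(cfg: KineticsSimConfig) -> tuple[list[TimeCourse], dict]:
    rng = np.random.default_rng(cfg.seed)
    times = np.arange(0.0, cfg.duration + 0.5 * cfg.interval, cfg.interval)
    courses: list[TimeCourse] = []
    truth: dict = {"true_rates": {}, "times": times}
    for cond, inhib in cfg.conditions.items():
        rate = cfg.v_true * (1.0 - inhib)
        truth["true_rates"][cond] = rate
        for rep in range(1, cfg.n_replicates + 1):
            conc = rate * times + rng.normal(0.0, cfg.noise_sd, size=times.size)
            if cfg.as_absorbance:
                readings = conc * cfg.standard_curve_slope
                kind = "absorbance"
            else:
                readings = conc
                kind = "concentration"
            courses.append(
                TimeCourse(
                    replicate=f"rep{rep}",
                    condition=cond,
                    times=times,
                    readings=readings,
                    reading_kind=kind,
                )
            )
    return courses, truth
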