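"""Synthetic LC-MS feature tables with known ground truth.

The generator emulates the statistical structure of a two-group untargeted
feature table: compounds drawn from a library emit features through the
adduct rules (each adduct with its own emission probability), observed m/z
carries ppm-scale multiplicative mass noise, intensities are log-normal
with a group effect confined to compounds of designated "active" pathways,
a block of unassigned noise features is added, and cells go missing
completely at random. Every random draw flows from one seed, so a
configuration reproduces its table bit-for-bit.

It does NOT emulate chromatographic peak shapes, correlated adduct
intensities, intensity-dependent missingness, or batch drift — conclusions
from these tables speak to the statistical machinery, not to raw-data
processing.

:func:`evaluate_against_truth` implements benchmark-style evaluation of a
detected feature table against a trusted feature list: greedy one-to-one
m/z + RT matching, fold-change accuracy at a relative-error bound, and a
count of matched, truly-changed features flagged significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .library import AdductRuleSet, CompoundPathwayLibrary, bundled_adduct_rules
from .peaktable import PeakTable

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_peak_table",
    "random_library",
    "evaluate_against_truth",
]

# Default adduct emission probabilities for negative mode: the deprotonated
# ion is almost always seen; satellite adducts/isotopes appear sporadically.
DEFAULT_EMISSION_PROBS = {
    "[M-H]-": 0.9,
    "[M-H2O-H]-": 0.2,
    "[M+Cl]-": 0.15,
    "[M+HCOO]-": 0.2,
    "[M(13C)-H]-": 0.25,
    "[M+H]+": 0.9,
    "[M+Na]+": 0.3,
    "[M+K]+": 0.15,
    "[M+NH4]+": 0.2,
    "[M-H2O+H]+": 0.2,
    "[M(13C)+H]+": 0.25,
}


@dataclass
class SimulationConfig:
    library: CompoundPathwayLibrary
    active_pathways: frozenset[str] = frozenset()
    effect_size: float = 1.0            # log2 shift of group A for active compounds
    n_samples_per_group: int = 12
    ppm_noise_sd: float = 2.0           # consistent with 5 ppm instrument accuracy
    rt_range: tuple[float, float] = (30.0, 1500.0)   # seconds
    ion_mode: str = "negative"
    adduct_emission_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EMISSION_PROBS))
    n_noise_features: int = 100
    missing_rate: float = 0.1
    intensity_log_mean: float = 10.0    # natural-log scale of log-normal intensities
    intensity_log_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples_per_group < 2:
            raise ValueError("need at least 2 samples per group")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        for label, p in self.adduct_emission_probs.items():
            if not (0 <= p <= 1):
                raise ValueError(f"emission probability for {label} outside [0, 1]")
        known = {pw.id for pw in self.library.pathways}
        bad = set(self.active_pathways) - known
        if bad:
            raise ValueError(f"active pathways not in library: {sorted(bad)}")


@dataclass
class GroundTruth:
    feature_compound: list[str]     # compound id or "noise", per feature
    feature_adduct: list[str]       # adduct label or "" for noise
    feature_fold_change: np.ndarray  # true group A / group B mean ratio
    active_pathways: frozenset[str]
    active_compounds: frozenset[str]

    def to_dataframe(self, pt: PeakTable) -> pd.DataFrame:
        return pd.DataFrame({
            "mz": pt.mz, "rt": pt.rt,
            "compound_id": self.feature_compound,
            "adduct": self.feature_adduct,
            "true_fold_change": self.feature_fold_change,
        })


def simulate_peak_table(
    cfg: SimulationConfig,
    rules: AdductRuleSet | None = None,
) -> tuple[PeakTable, GroundTruth]:
    """Generate a two-group peak table plus its ground truth.

    Compounds in active pathways have their group-A intensities multiplied
    by 2**effect_size on every feature they emit, so the true fold change
    (A/B) of those features is 2**effect_size; all other features have true
    fold change 1.
    """
    if len(cfg.library.pathways) < 2:
        raise ValueError("library must contain at least 2 pathways")
    rules = rules if rules is not None else bundled_adduct_rules()
    rng = np.random.default_rng(cfg.seed)
    mode_rules = rules.for_mode(cfg.ion_mode)
    n_per = cfg.n_samples_per_group
    n_samples = 2 * n_per

    active_compounds: set[str] = set()
    for pw in cfg.library.pathways:
        if pw.id in cfg.active_pathways:
            active_compounds |= set(pw.compound_ids)

    mz_list: list[float] = []
    src_compound: list[str] = []
    src_adduct: list[str] = []
    true_fc: list[float] = []
    rows: list[np.ndarray] = []
    factor = 2.0 ** cfg.effect_size

    for cid in sorted(cfg.library.compounds):
        cpd = cfg.library.compounds[cid]
        is_active = cid in active_compounds
        for rule in mode_rules:
            prob = cfg.adduct_emission_probs.get(rule.label, 0.0)
            if rng.random() >= prob:
                continue
            theo = rule.mz(cpd.monoisotopic_mass)
            eps = rng.normal(0.0, cfg.ppm_noise_sd * 1e-6)
            mz_list.append(theo * (1.0 + eps))
            src_compound.append(cid)
            src_adduct.append(rule.label)
            base = rng.lognormal(cfg.intensity_log_mean, cfg.intensity_log_sd / 4)
            noise = rng.lognormal(0.0, cfg.intensity_log_sd, size=n_samples)
            row = base * noise
            if is_active:
                row[:n_per] *= factor
            rows.append(row)
            true_fc.append(factor if is_active else 1.0)

    if mz_list:
        lo_mz, hi_mz = 0.8 * min(mz_list), 1.2 * max(mz_list)
    else:
        lo_mz, hi_mz = 80.0, 1000.0
    for _ in range(cfg.n_noise_features):
        mz_list.append(rng.uniform(lo_mz, hi_mz))
        src_compound.append("noise")
        src_adduct.append("")
        base = rng.lognormal(cfg.intensity_log_mean, cfg.intensity_log_sd / 4)
        rows.append(base * rng.lognormal(0.0, cfg.intensity_log_sd, size=n_samples))
        true_fc.append(1.0)

    if not rows:
        raise ValueError("degenerate configuration: no features emitted")
    X = np.vstack(rows)
    if cfg.missing_rate > 0:
        X[rng.random(X.shape) < cfg.missing_rate] = np.nan
    rt = rng.uniform(cfg.rt_range[0], cfg.rt_range[1], size=len(mz_list))
    pt = PeakTable(
        np.array(mz_list), rt, X,
        sample_ids=[f"A{i+1}" for i in range(n_per)] + [f"B{i+1}" for i in range(n_per)],
        group_labels=["A"] * n_per + ["B"] * n_per,
    )
    truth = GroundTruth(
        feature_compound=src_compound,
        feature_adduct=src_adduct,
        feature_fold_change=np.array(true_fc),
        active_pathways=frozenset(cfg.active_pathways),
        active_compounds=frozenset(active_compounds),
    )
    return pt, truth


def random_library(
    n_compounds: int = 200,
    n_pathways: int = 10,
    pathway_size: int = 20,
    seed: int = 0,
    disjoint: bool = False,
) -> CompoundPathwayLibrary:
    """Generate a random CHNO compound library with random pathway sets.

    Compounds get random small-molecule formulas (C4-C40 backbones with
    matching H, O and optional N), so masses spread realistically over
    ~100-700 Da. Pathways are random compound sets; with ``disjoint`` they
    partition the compound list (no shared compounds), which removes
    between-pathway dependence in simulation studies.
    """
    from .chem import monoisotopic_mass
    from .library import Compound, PathwaySet

    if disjoint and n_pathways * pathway_size > n_compounds:
        raise ValueError("disjoint pathways need n_pathways * pathway_size <= n_compounds")
    rng = np.random.default_rng(seed)
    compounds: dict[str, Compound] = {}
    for i in range(n_compounds):
        c = int(rng.integers(4, 40))
        h = int(rng.integers(c, 2 * c + 2))
        o = int(rng.integers(1, 10))
        n = int(rng.integers(0, 4))
        formula = f"C{c}H{h}" + (f"N{n}" if n else "") + f"O{o}"
        cid = f"S{i:04d}"
        compounds[cid] = Compound(cid, cid, formula, monoisotopic_mass(formula))
    ids = sorted(compounds)
    if disjoint:
        perm = rng.permutation(ids)
        sets = [perm[j * pathway_size:(j + 1) * pathway_size].tolist()
                for j in range(n_pathways)]
    else:
        sets = [rng.choice(ids, pathway_size, replace=False).tolist()
                for j in range(n_pathways)]
    pathways = [PathwaySet(f"pw{j:03d}", f"pathway {j}", frozenset(s))
                for j, s in enumerate(sets)]
    return CompoundPathwayLibrary(name=f"random-{seed}", compounds=compounds,
                                  pathways=pathways)


def evaluate_against_truth(
    detected: pd.DataFrame,
    truth: pd.DataFrame,
    ppm_tol: float = 10.0,
    rt_tol_min: float = 0.3,
    fc_rel_err: float = 0.2,
) -> dict:
    """Score a detected feature table against a trusted feature list.

    ``detected`` needs columns mz, rt and optionally fold_change and
    significant; ``truth`` needs mz, rt, fold_change. Matching is greedy
    one-to-one by ascending |ppm| among pairs within both the ppm and the
    RT tolerance (RT tolerance given in minutes, RT columns in seconds).

    Returns a dict with ``matched``, ``accurately_quantified`` (relative
    fold-change error < ``fc_rel_err`` among matched) and ``discriminating``
    (matched, true fold change != 1, flagged significant).
    """
    if truth.empty:
        raise ValueError("truth list is empty")
    rt_tol = rt_tol_min * 60.0
    det_mz = detected["mz"].to_numpy(dtype=float)
    det_rt = detected["rt"].to_numpy(dtype=float)
    tr_mz = truth["mz"].to_numpy(dtype=float)
    tr_rt = truth["rt"].to_numpy(dtype=float)

    pairs = []  # (|ppm|, truth_idx, det_idx)
    for ti in range(len(tr_mz)):
        ppm = (det_mz - tr_mz[ti]) / tr_mz[ti] * 1e6
        ok = (np.abs(ppm) <= ppm_tol) & (np.abs(det_rt - tr_rt[ti]) <= rt_tol)
        for di in np.flatnonzero(ok):
            pairs.append((abs(float(ppm[di])), ti, int(di)))
    pairs.sort()
    used_t: set[int] = set()
    used_d: set[int] = set()
    assignment: dict[int, int] = {}
    for _, ti, di in pairs:
        if ti in used_t or di in used_d:
            continue
        used_t.add(ti)
        used_d.add(di)
        assignment[ti] = di

    matched = len(assignment)
    quantified = 0
    discriminating = 0
    det_fc = detected["fold_change"].to_numpy(dtype=float) if "fold_change" in detected else None
    det_sig = detected["significant"].to_numpy(dtype=bool) if "significant" in detected else None
    tr_fc = truth["fold_change"].to_numpy(dtype=float) if "fold_change" in truth else None
    for ti, di in assignment.items():
        if det_fc is not None and tr_fc is not None:
            if abs(det_fc[di] - tr_fc[ti]) / tr_fc[ti] < fc_rel_err:
                quantified += 1
            if tr_fc[ti] != 1.0 and det_sig is not None and det_sig[di]:
                discriminating += 1
    return {
        "matched": matched,
        "accurately_quantified": quantified,
        "discriminating": discriminating,
        "n_truth": len(tr_mz),
        "n_detected": len(det_mz),
    }
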