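"""Synthetic FIE-MS study generator with known ground truth.

Emulates a two-garden / multi-timepoint tea-leaf fingerprinting design:
class-structured log-normal bin intensities with a small planted set of
discriminating bins, diurnal trend archetypes across four sampling times
(09:00, 12:00, 18:00, 00:00 mapped to hours 0/3/9/15 of a single day),
pooled-QC technical replicates with low relative s.d., detection-limit
dropout (zeros) in the low-intensity tail, and a toy compound / taxonomy /
pathway reference for annotation and enrichment.  Every generator is a pure
function of (spec, seed), so downstream null-calibration and recovery
properties can be tested against exact ground truth.

The latent model is additive on the log2 scale (multiplicative log-normal on
the raw scale, the standard noise model for MS intensities):

    log2 x[s, b] = baseline[b] + class_shift[b] * 1{group(s) = target}
                   + archetype[b][time(s)] + N(0, noise_sd)

with baseline drawn log-uniform (log2 in [10, 20], i.e. raw 2^10..2^20).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import (DEFAULT_ADDUCTS, FormulaDB, formula_mass,
                         theoretical_mz)
from .binning import (BIN_WIDTH, MZ_RANGE, NEGATIVE, POSITIVE, FeatureMatrix,
                      Scan, ScanSet, bin_id, bin_index)

logger = logging.getLogger("leafprint")

#: diurnal sampling design: clock label -> hours since first sampling
DEFAULT_TIMEPOINTS: tuple[tuple[str, float], ...] = (
    ("09:00", 0.0), ("12:00", 3.0), ("18:00", 9.0), ("00:00", 15.0))

#: five trend archetypes (log2 offsets per timepoint); the first is the
#: rise-then-fall diurnal shape (peak at 18:00, overnight depletion below the
#: morning baseline, as photosynthesis-driven sugars behave).  Offsets of any
#: one archetype keep all four timepoints mutually separated by at least one
#: log2 unit so that sampling hour stays identifiable from its features.
DEFAULT_ARCHETYPES: tuple[tuple[float, ...], ...] = (
    (0.0, 1.0, 2.0, -1.0),       # rise then fall (diurnal)
    (0.0, 0.5, 1.0, 1.5),        # monotone rise
    (0.0, -0.5, -1.0, -1.5),     # monotone fall
    (0.0, -1.0, -2.0, -1.0),     # fall then rise
    (0.0, 0.3, 0.3, -1.0),       # plateau then night drop
)


@dataclass
class SyntheticSpec:
    """Design of a synthetic fingerprinting study.

    Defaults mirror the emulated field design: two gardens x 24 samples,
    four diurnal timepoints, 500 bins with 10 discriminating bins planted at
    a 3x-noise log2 shift, five trend archetypes of 20 bins each, five
    pooled-QC injections at 10% RSD.
    """

    classes: tuple[str, ...] = ("garden3", "garden4")
    n_per_class: int = 24
    timepoints: tuple[tuple[str, float], ...] = DEFAULT_TIMEPOINTS
    n_features: int = 500
    n_discriminating: int = 10
    effect_size: float = 0.9          # log2 shift of planted class bins
    trend_archetypes: tuple[tuple[float, ...], ...] = DEFAULT_ARCHETYPES
    n_trend_features_per_archetype: int = 20
    noise_sd: float = 0.3             # log2-scale residual s.d.
    qc_n: int = 5
    qc_rsd: float = 0.10              # target pooled-QC relative s.d.
    zero_rate: float = 0.10           # P(zero | below detection threshold)
    dropout_quantile: float = 0.25    # intensity quantile defining "below threshold"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.classes) < 1 or len(set(self.classes)) != len(self.classes):
            raise ValueError("classes: need at least one distinct class label")
        if self.n_per_class < 1:
            raise ValueError("n_per_class: must be >= 1")
        if self.n_features < 1:
            raise ValueError("n_features: must be >= 1")
        n_trend = len(self.trend_archetypes) * self.n_trend_features_per_archetype
        if self.n_discriminating + n_trend > self.n_features:
            raise ValueError(
                "n_discriminating + total trend features exceeds n_features")
        if self.n_discriminating < 0:
            raise ValueError("n_discriminating: must be >= 0")
        if self.effect_size < 0:
            raise ValueError("effect_size: must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd: must be > 0")
        if not (0 <= self.zero_rate < 1):
            raise ValueError("zero_rate: must be in [0, 1)")
        if not (0 <= self.dropout_quantile <= 1):
            raise ValueError("dropout_quantile: must be in [0, 1]")
        if self.qc_n < 0:
            raise ValueError("qc_n: must be >= 0")
        if self.qc_rsd < 0:
            raise ValueError("qc_rsd: must be >= 0")
        hours = [h for _, h in self.timepoints]
        if any(b <= a for a, b in zip(hours, hours[1:])):
            raise ValueError("timepoints: hour offsets must be strictly increasing")
        for arch in self.trend_archetypes:
            if len(arch) != len(self.timepoints):
                raise ValueError(
                    "trend_archetypes: each archetype needs one offset per timepoint")

    @property
    def n_samples(self) -> int:
        return len(self.classes) * self.n_per_class


@dataclass
class GroundTruth:
    """What was planted: discriminating bins, trend bins, compound-backed bins."""

    discriminating: pd.DataFrame   # bin_id, class_label, log2_shift
    trend_bins: pd.DataFrame       # bin_id, archetype (index into spec archetypes)
    compound_truth: pd.DataFrame   # bin_id, compound_id, formula, adduct, mode, theoretical_mz

    @property
    def discriminating_bins(self) -> list[str]:
        return list(self.discriminating["bin_id"])

    def trend_bin_map(self) -> dict[str, int]:
        return dict(zip(self.trend_bins["bin_id"], self.trend_bins["archetype"]))


# ---------------------------------------------------------------------------
# metadata
# ---------------------------------------------------------------------------

def generate_metadata(spec: SyntheticSpec) -> pd.DataFrame:
    """One row per biological sample plus the pooled-QC injections.

    Timepoints are assigned round-robin within each class; run order is a
    seeded random permutation over all injections.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    i = 0
    for cls in spec.classes:
        for j in range(spec.n_per_class):
            label, hour = spec.timepoints[j % len(spec.timepoints)]
            rows.append({"sample_id": f"S{i:03d}", "role": "sample",
                         "group": cls, "timepoint": label, "hour": hour,
                         "batch": 1})
            i += 1
    for q in range(spec.qc_n):
        rows.append({"sample_id": f"QC{q:02d}", "role": "QC", "group": "",
                     "timepoint": "", "hour": np.nan, "batch": 1})
    meta = pd.DataFrame(rows)
    meta["run_order"] = rng.permutation(len(meta)) + 1
    return meta


# ---------------------------------------------------------------------------
# feature matrix
# ---------------------------------------------------------------------------

def _choose_bins(spec: SyntheticSpec, rng: np.random.Generator,
                 reference: FormulaDB | None,
                 bin_width: float) -> tuple[list[str], pd.DataFrame, pd.DataFrame]:
    """Pick bin ids / modes / accurate m/z, planting compound-backed bins first."""
    lo_k = bin_index(MZ_RANGE[0], bin_width) + 1
    hi_k = bin_index(MZ_RANGE[1], bin_width) - 1
    ids, modes, mzs = [], [], []
    truth_rows = []
    used: set[tuple[str, int]] = set()

    if reference is not None:
        for _, row in reference.table.iterrows():
            if len(ids) >= spec.n_features:
                break
            counts_ok = [r for r in DEFAULT_ADDUCTS if r.applicable(row["formula"])]
            # deterministic adduct choice: protonation first
            pref = {"[M+H]+": 0, "[M-H]-": 1}
            counts_ok.sort(key=lambda r: pref.get(r.name, 2))
            planted = False
            for rule in counts_ok:
                tm = theoretical_mz(row["mass"], rule)
                if not (MZ_RANGE[0] <= tm < MZ_RANGE[1]):
                    continue
                k = int(bin_index(tm, bin_width))
                mode = rule.polarity
                # keep the ion at least 0.1 bin widths from a bin edge so that
                # small centroid jitter cannot cross into a neighbouring bin
                margin = min(tm - k * bin_width, (k + 1) * bin_width - tm)
                if margin < 0.1 * bin_width or (mode, k) in used:
                    continue
                used.add((mode, k))
                bid = bin_id(mode, k, bin_width)
                ids.append(bid); modes.append(mode); mzs.append(tm)
                truth_rows.append({"bin_id": bid, "compound_id": row["compound_id"],
                                   "formula": row["formula"], "adduct": rule.name,
                                   "mode": mode, "theoretical_mz": tm})
                planted = True
                break
            if not planted:
                logger.info("reference compound %s not planted (no safe bin)",
                            row["compound_id"])

    while len(ids) < spec.n_features:
        mode = POSITIVE if rng.random() < 0.5 else NEGATIVE
        k = int(rng.integers(lo_k, hi_k))
        if (mode, k) in used:
            continue
        used.add((mode, k))
        # accurate m/z away from bin edges (margin 0.2 widths)
        mz = (k + 0.5 + float(rng.uniform(-0.3, 0.3))) * bin_width
        ids.append(bin_id(mode, k, bin_width)); modes.append(mode); mzs.append(mz)

    info = pd.DataFrame({"mode": modes, "mz": mzs}, index=ids)
    truth = pd.DataFrame(truth_rows, columns=["bin_id", "compound_id", "formula",
                                              "adduct", "mode", "theoretical_mz"])
    return ids, info, truth


def generate_feature_matrix(spec: SyntheticSpec,
                            reference: FormulaDB | None = None,
                            bin_width: float = BIN_WIDTH
                            ) -> tuple[FeatureMatrix, GroundTruth, pd.DataFrame]:
    """Generate the raw-scale intensity matrix, its ground truth and metadata.

    When a ``reference`` is supplied, the first bins are placed at the exact
    theoretical m/z of one electrospray ion per reference compound, so that
    downstream accurate-mass annotation can be validated against truth.
    """
    rng = np.random.default_rng(spec.seed)
    meta = generate_metadata(spec)
    bio = meta[meta["role"] == "sample"].reset_index(drop=True)

    ids, info, compound_truth = _choose_bins(spec, rng, reference, bin_width)
    nf = spec.n_features

    baseline = rng.uniform(10.0, 20.0, size=nf)

    n_arch = len(spec.trend_archetypes)
    n_per_arch = spec.n_trend_features_per_archetype
    if reference is not None and n_arch and len(compound_truth):
        # pathway-coherent trends: compounds of one pathway share an
        # archetype, as co-regulated pathway members do in real diurnal
        # data — this is what makes cluster-level enrichment detectable
        trend_sets: list[list[int]] = [[] for _ in range(n_arch)]
        cpd_bin_pos = {bid: ids.index(bid) for bid in compound_truth["bin_id"]}
        primary_pw = dict(zip(reference.table["compound_id"],
                              reference.table["pathway_ids"].map(
                                  lambda p: p[0] if p else "")))
        pathways = sorted({primary_pw[c] for c in compound_truth["compound_id"]
                           if primary_pw[c]})
        for _, row in compound_truth.iterrows():
            pw = primary_pw[row["compound_id"]]
            if not pw:
                continue
            a = pathways.index(pw) % n_arch
            if len(trend_sets[a]) < n_per_arch:
                trend_sets[a].append(cpd_bin_pos[row["bin_id"]])
        used = {i for s in trend_sets for i in s}
        free = [i for i in rng.permutation(nf) if i not in used]
        for a in range(n_arch):
            while len(trend_sets[a]) < n_per_arch:
                trend_sets[a].append(free.pop())
        trend_idx = [np.array(s, dtype=int) for s in trend_sets]
        disc_idx = np.array(free[:spec.n_discriminating], dtype=int)
    else:
        perm = rng.permutation(nf)
        disc_idx = perm[:spec.n_discriminating]
        trend_idx = [perm[spec.n_discriminating + a * n_per_arch:
                          spec.n_discriminating + (a + 1) * n_per_arch]
                     for a in range(n_arch)]

    # planted class shifts: alternate sign bin by bin, applied to the last class
    target = spec.classes[-1]
    signs = np.array([1.0 if i % 2 == 0 else -1.0
                      for i in range(spec.n_discriminating)])
    shift = np.zeros(nf)
    shift[disc_idx] = signs * spec.effect_size

    tp_index = {label: t for t, (label, _) in enumerate(spec.timepoints)}
    arch_offsets = np.zeros((len(spec.timepoints), nf))
    for a, idx in enumerate(trend_idx):
        for t in range(len(spec.timepoints)):
            arch_offsets[t, idx] = spec.trend_archetypes[a][t]

    latent = np.tile(baseline, (len(bio), 1))
    is_target = (bio["group"] == target).to_numpy()
    latent[is_target] += shift
    t_of_sample = bio["timepoint"].map(tp_index).to_numpy()
    latent += arch_offsets[t_of_sample]
    latent += rng.normal(0.0, spec.noise_sd, size=latent.shape)
    raw = np.exp2(latent)

    # detection-limit dropout: only the low-intensity tail can be zeroed
    if spec.zero_rate > 0 and spec.dropout_quantile > 0:
        thresh = np.quantile(raw, spec.dropout_quantile)
        candidates = raw < thresh
        zeros = candidates & (rng.random(raw.shape) < spec.zero_rate)
        raw[zeros] = 0.0

    # pooled QC: multiplicative noise around the per-bin grand mean
    grand = raw.mean(axis=0)
    qc = grand * (1.0 + rng.normal(0.0, spec.qc_rsd, size=(spec.qc_n, nf)))
    qc = np.clip(qc, 0.0, None)

    data = pd.DataFrame(np.vstack([raw, qc]) if spec.qc_n else raw,
                        index=list(bio["sample_id"]) +
                              list(meta.loc[meta["role"] == "QC", "sample_id"]),
                        columns=ids)
    fm = FeatureMatrix(data, info, stage="raw")

    disc = pd.DataFrame({"bin_id": [ids[i] for i in disc_idx],
                         "class_label": target,
                         "log2_shift": signs * spec.effect_size})
    trend = pd.DataFrame({"bin_id": [ids[i] for a in range(n_arch) for i in trend_idx[a]],
                          "archetype": [a for a in range(n_arch)
                                        for _ in trend_idx[a]]})
    truth = GroundTruth(discriminating=disc, trend_bins=trend,
                        compound_truth=compound_truth)
    return fm, truth, meta


# ---------------------------------------------------------------------------
# scan-level emulation
# ---------------------------------------------------------------------------

def triangular_weights(n_scans: int) -> np.ndarray:
    """Symmetric triangular infusion profile over ``n_scans`` scans."""
    s = np.arange(n_scans, dtype=float)
    return np.minimum(s + 1, n_scans - s)


def matrix_to_scans(matrix: FeatureMatrix, centroid_jitter_ppm: float = 0.0,
                    n_scans: int = 5, seed: int = 0,
                    bin_width: float = BIN_WIDTH,
                    tic_fraction: float = 0.5) -> dict[str, ScanSet]:
    """Expand a raw matrix into per-sample centroided scan sets.

    Each bin's intensity is spread across ``n_scans`` scans following a
    triangular infusion profile, scaled so that averaging the scans inside
    the ``tic_fraction`` infusion window (the window ``select_infusion_scans``
    picks with the same fraction) returns the original value.  Centroid m/z
    values are jittered uniformly within +-``centroid_jitter_ppm`` around the
    bin's accurate m/z.
    """
    if matrix.stage != "raw":
        raise ValueError("matrix_to_scans expects a raw-stage matrix")
    if n_scans < 1:
        raise ValueError("n_scans must be >= 1")
    mz_max = float(matrix.bin_info["mz"].max())
    if centroid_jitter_ppm * 1e-6 * mz_max > bin_width / 2:
        raise ValueError(
            f"jitter {centroid_jitter_ppm} ppm exceeds half a bin width at "
            f"m/z {mz_max:.2f}; round-trip bin identity would be lost")

    w = triangular_weights(n_scans)
    in_window = w >= tic_fraction * w.max()
    w = w / w[in_window].mean()  # window average of weights == 1

    rng = np.random.default_rng(seed)
    modes = matrix.bin_info["mode"].to_numpy()
    mz0 = matrix.bin_info["mz"].to_numpy()
    out: dict[str, ScanSet] = {}
    for sid in matrix.sample_ids:
        values = matrix.data.loc[sid].to_numpy()
        scans = []
        for mode in (POSITIVE, NEGATIVE):
            sel = (modes == mode) & (values > 0)
            if not sel.any():
                continue
            base_mz = mz0[sel]
            vals = values[sel]
            for s in range(n_scans):
                jitter = rng.uniform(-1.0, 1.0, size=base_mz.size) \
                    * centroid_jitter_ppm * 1e-6 * base_mz
                scans.append(Scan(mode, s, base_mz + jitter, vals * w[s]))
        out[sid] = ScanSet(sample_id=sid, scans=scans)
    return out


# ---------------------------------------------------------------------------
# toy compound / taxonomy / pathway reference
# ---------------------------------------------------------------------------

_SUPERCLASSES = (
    "Phenylpropanoids and polyketides",
    "Organic oxygen compounds",
    "Organic acids and derivatives",
    "Lipids and lipid-like molecules",
    "Benzenoids",
    "Organoheterocyclic compounds",
)


def generate_reference(n_compounds: int = 40, n_pathways: int = 5,
                       taxonomy_depth: int = 4, seed: int = 0,
                       fallback_fraction: float = 0.2
                       ) -> tuple[FormulaDB, pd.DataFrame]:
    """Generate a toy compound table and compound-reaction-pathway edge list.

    Compounds receive distinct CHNO(S/P) formulas; monoisotopic masses come
    from the compiled-in atomic mass table.  Each compound gets a taxonomy
    lineage of ``taxonomy_depth`` terms rooted at "Organic compounds" and
    membership edges to pathways routed through reaction nodes.
    """
    if n_compounds < 1 or n_pathways < 1 or taxonomy_depth < 1:
        raise ValueError("counts must be positive")
    rng = np.random.default_rng(seed)

    # enumerate a deterministic grid of candidate formulas, then subsample
    grid = [(c, h, o, n)
            for c in range(5, 31) for h in range(c // 2, 2 * c + 3)
            for o in range(0, 13) for n in range(0, 5)]
    if n_compounds > len(grid):
        raise ValueError(
            f"cannot generate {n_compounds} distinct formulas "
            f"(capacity {len(grid)})")
    chosen = rng.choice(len(grid), size=n_compounds, replace=False)

    rows = []
    for i, gi in enumerate(sorted(chosen)):
        c, h, o, n = grid[gi]
        formula = f"C{c}H{h}" + (f"N{n}" if n else "") + (f"O{o}" if o else "")
        mass = formula_mass(formula)
        pw = sorted(set(f"path{int(p):02d}" for p in
                        rng.choice(n_pathways, size=int(rng.integers(1, 3)),
                                   replace=False)))
        # pathway members share chemistry: the primary pathway fixes the
        # superclass (flavonoid pathways hold flavonoids, etc.)
        sclass = _SUPERCLASSES[int(pw[0][4:]) % len(_SUPERCLASSES)]
        lineage = ["Organic compounds", sclass]
        node = sclass
        for depth in range(2, taxonomy_depth):
            node = f"{node.split(' ')[0]} class L{depth}.{int(rng.integers(2))}"
            lineage.append(node)
        lineage = lineage[:taxonomy_depth]
        rows.append({"compound_id": f"cpd{i:03d}", "formula": formula,
                     "mass": mass,
                     "source": "fallback" if rng.random() < fallback_fraction
                               else "primary",
                     "lineage": lineage, "pathway_ids": pw})
    db = FormulaDB(pd.DataFrame(rows))

    # route each compound-pathway membership through a reaction node
    edges = []
    rxn_counter = itertools.count()
    for pw in sorted({p for r in rows for p in r["pathway_ids"]}):
        members = [r["compound_id"] for r in rows if pw in r["pathway_ids"]]
        for j in range(0, len(members), 2):
            rid = f"rxn{next(rxn_counter):03d}"
            for cid in members[j:j + 2]:
                edges.append({"source": cid, "target": rid})
            edges.append({"source": rid, "target": pw})
    edge_df = pd.DataFrame(edges, columns=["source", "target"])
    return db, edge_df
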