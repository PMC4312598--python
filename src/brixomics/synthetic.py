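"""Synthetic data with the statistical structure of a late-ripening berry study.

Generates every input the analysis consumes — a log2 expression matrix on a
4 °Brix x 2 tissue x 6 replicate factorial design, replicate outliers, GO
annotations with planted overrepresentation, probe/target sequences with
off-target alignment hits, and standard-addition response tables — together
with the ground truth needed to score recovery.

Expression is simulated directly on the log2 scale (RMA-like measures):
per-gene baseline plus an archetype profile over the (brix, tissue) grid
plus Gaussian replicate noise, clipped to [0, 16].  Archetype shapes mirror
the cluster morphologies seen in ripening studies: monotone ramps across
°Brix, a skin-specific peak at the second °Brix level, a skin valley, and a
constant tissue offset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import ExpressionExperiment, condition_label

__all__ = [
    "ARCHETYPES", "SimulationConfig", "OutlierSpec", "GroundTruth",
    "simulate_expression_experiment", "plant_outliers",
    "simulate_go_annotation", "simulate_probe_hits",
    "simulate_standard_addition", "archetype_profile", "archetype_effects",
]

LOG2_MIN, LOG2_MAX = 0.0, 16.0

# Sub-stream labels hashed off the global seed so the generators are
# independent but jointly reproducible.
_STREAMS = {"expression": 0, "outliers": 1, "go": 2, "probes": 3, "quant": 4}


def child_rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(
        entropy=int(seed), spawn_key=(_STREAMS[stream],)))


# ---------------------------------------------------------------------------
# Archetype profile library
# ---------------------------------------------------------------------------

def _ramp(i: int, n: int) -> float:
    return i / (n - 1) if n > 1 else 0.0


def _peak(i: int, at: int, n: int) -> float:
    # triangular bump centred on level `at`
    width = max(at, n - 1 - at, 1)
    return max(0.0, 1.0 - abs(i - at) / width)


# Each archetype maps (brix index, n brix levels, tissue index) -> log2 offset
# per unit amplitude.  Tissue index 0 is the first tissue in the config
# (skin by default).
# Tissue-biased shapes keep a damped copy of the pattern in the second
# tissue: transcripts peaking in the skin are rarely silent in the pulp,
# and the residual pattern is what makes the shapes separable by rank.
ARCHETYPES: dict[str, Callable[[int, int, int], float]] = {
    "flat": lambda i, n, t: 0.0,
    "monotone_decrease": lambda i, n, t: -_ramp(i, n),
    "monotone_increase": lambda i, n, t: _ramp(i, n),
    "skin_peak": lambda i, n, t: _peak(i, 1, n) * (1.0 if t == 0 else 0.3),
    "valley": lambda i, n, t: -_peak(i, 1, n) * (1.0 if t == 0 else 0.3),
    "tissue_offset": lambda i, n, t: 1.0 if t == 0 else 0.0,
}


def archetype_profile(name: str, amplitude: float, brix_levels: Sequence[float],
                      tissues: Sequence[str]) -> np.ndarray:
    """Noise-free condition profile (brix-major order) for one archetype."""
    fn = ARCHETYPES[name]
    n = len(brix_levels)
    return np.array([amplitude * fn(i, n, t)
                     for i in range(n) for t in range(len(tissues))])


def archetype_effects(name: str, amplitude: float,
                      brix_levels: Sequence[float],
                      tissues: Sequence[str]) -> dict[str, bool]:
    """True factorial effect indicators implied by an archetype shape.

    Derived numerically from the noise-free profile: a brix (tissue) effect
    exists when marginal means vary, an interaction when the profile is not
    additive in the two factors.
    """
    prof = archetype_profile(name, amplitude, brix_levels, tissues)
    grid = prof.reshape(len(brix_levels), len(tissues))
    bm = grid.mean(axis=1)
    tm = grid.mean(axis=0)
    additive = bm[:, None] + tm[None, :] - grid.mean()
    tol = 1e-12
    return {
        "brix": bool(np.ptp(bm) > tol),
        "tissue": bool(np.ptp(tm) > tol),
        "interaction": bool(np.max(np.abs(grid - additive)) > tol),
    }


# ---------------------------------------------------------------------------
# Configuration and ground truth
# ---------------------------------------------------------------------------

@dataclass
class OutlierSpec:
    """Fractions of replicate sets receiving displaced values.

    Displacement is expressed in multiples of the set's pre-displacement
    standard deviation, with random sign per value.
    """

    frac_single: float = 0.003
    frac_double: float = 0.001
    displacement_sd: float = 3.0

    def __post_init__(self) -> None:
        for f in (self.frac_single, self.frac_double):
            if not 0.0 <= f <= 1.0:
                raise ValueError("outlier fractions must be in [0, 1]")
        if self.displacement_sd <= 0:
            raise ValueError("displacement must be positive")


@dataclass
class SimulationConfig:
    """Study design and generative parameters for the synthetic experiment.

    Defaults follow the 4 °Brix x 2 tissue x 6 biological replicate design
    with ~29,549 array features.
    """

    n_genes: int = 29549
    brix_levels: tuple[float, ...] = (22.6, 23.2, 25.0, 36.7)
    tissues: tuple[str, ...] = ("skin", "pulp")
    n_replicates: int = 6
    # archetype name -> (fraction of genes, amplitude in log2 units)
    effect_model: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "flat": (0.40, 0.0),
            "monotone_decrease": (0.15, 2.0),
            "monotone_increase": (0.15, 2.0),
            "tissue_offset": (0.15, 2.0),
            "skin_peak": (0.08, 2.0),
            "valley": (0.07, 2.0),
        })
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    noise_sd: float = 0.25
    outlier_spec: OutlierSpec = field(default_factory=OutlierSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_replicates < 2:
            raise ValueError("need n_genes > 0 and n_replicates >= 2")
        if list(self.brix_levels) != sorted(set(self.brix_levels)):
            raise ValueError("brix_levels must be strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not self.effect_model:
            raise ValueError("effect model must name at least one archetype")
        unknown = set(self.effect_model) - set(ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown archetypes: {sorted(unknown)}")


@dataclass
class GroundTruth:
    """What was planted, so downstream recovery can be scored."""

    archetype: pd.Series | None = None          # gene -> archetype name
    effects: pd.DataFrame | None = None         # gene x {brix,tissue,interaction}
    outlier_positions: list[tuple[str, float, str, int]] = field(
        default_factory=list)                   # (gene, brix, tissue, replicate)
    enriched_terms: dict[str, float] = field(default_factory=dict)
    significant_set: list[str] = field(default_factory=list)
    crosshyb_genes: dict[str, bool] = field(default_factory=dict)
    true_concentration: float | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "archetype": None if self.archetype is None
            else self.archetype.to_dict(),
            "effects": None if self.effects is None
            else {c: self.effects[c].astype(bool).to_dict()
                  for c in self.effects.columns},
            "outlier_positions": [list(p) for p in self.outlier_positions],
            "enriched_terms": self.enriched_terms,
            "significant_set": self.significant_set,
            "crosshyb_genes": self.crosshyb_genes,
            "true_concentration": self.true_concentration,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def _assign_archetypes(config: SimulationConfig,
                       rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Largest-remainder allocation of genes to archetypes, then shuffled."""
    names = list(config.effect_model)
    fracs = np.array([config.effect_model[a][0] for a in names], dtype=float)
    if fracs.sum() <= 0:
        raise ValueError("archetype fractions must sum to a positive value")
    fracs = fracs / fracs.sum()
    raw = fracs * config.n_genes
    counts = np.floor(raw).astype(int)
    rem = config.n_genes - counts.sum()
    for i in np.argsort(-(raw - counts))[:rem]:
        counts[i] += 1
    labels = np.repeat(np.arange(len(names)), counts)
    rng.shuffle(labels)
    return np.array(names), labels


def simulate_expression_experiment(
        config: SimulationConfig) -> tuple[ExpressionExperiment, GroundTruth]:
    """Simulate the factorial log2 expression matrix and its ground truth."""
    rng = child_rng(config.seed, "expression")
    names, labels = _assign_archetypes(config, rng)
    B, T, R = len(config.brix_levels), len(config.tissues), config.n_replicates
    n_cond = B * T

    profiles = np.stack([
        archetype_profile(a, config.effect_model[a][1],
                          config.brix_levels, config.tissues)
        for a in names])                                   # archetype x cond
    baseline = rng.normal(config.baseline_mean, config.baseline_sd,
                          size=config.n_genes)
    mu = baseline[:, None] + profiles[labels]              # gene x cond
    noise = rng.normal(0.0, config.noise_sd,
                       size=(config.n_genes, n_cond, R)) if config.noise_sd > 0 \
        else np.zeros((config.n_genes, n_cond, R))
    values = np.clip(mu[:, :, None] + noise, LOG2_MIN, LOG2_MAX)
    values = values.reshape(config.n_genes, n_cond * R)

    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    sample_ids, design_rows = [], []
    for bi, brix in enumerate(config.brix_levels):
        for ti, tissue in enumerate(config.tissues):
            for rep in range(1, R + 1):
                sid = f"{condition_label(brix, tissue)}_{rep}"
                sample_ids.append(sid)
                design_rows.append((sid, brix, tissue, rep))
    design = pd.DataFrame(design_rows,
                          columns=["sample_id", "brix", "tissue", "replicate"]
                          ).set_index("sample_id")
    experiment = ExpressionExperiment(
        pd.DataFrame(values, index=genes, columns=sample_ids), design)

    arche = pd.Series([names[l] for l in labels], index=genes, name="archetype")
    eff_by_arch = {a: archetype_effects(a, config.effect_model[a][1],
                                        config.brix_levels, config.tissues)
                   for a in names}
    effects = pd.DataFrame(
        [eff_by_arch[arche[g]] for g in genes], index=genes)
    truth = GroundTruth(archetype=arche, effects=effects)
    return experiment, truth


def plant_outliers(experiment: ExpressionExperiment,
                   outlier_spec: OutlierSpec,
                   seed: int) -> tuple[ExpressionExperiment, GroundTruth]:
    """Displace replicate values in randomly chosen sets; record positions.

    Single-outlier sets get one value displaced by
    ``displacement_sd`` x (pre-displacement set SD), double-outlier sets two
    values displaced in opposite directions; signs are random.
    """
    if outlier_spec.frac_single + outlier_spec.frac_double > 1.0:
        raise ValueError("outlier fractions sum above 1")
    if experiment.design.groupby(["brix", "tissue"]).size().min() < 2:
        raise ValueError("outlier planting needs >= 2 replicates per set")
    rng = child_rng(seed, "outliers")
    out = experiment.copy()
    conditions = experiment.conditions
    genes = experiment.genes
    n_sets = len(genes) * len(conditions)
    n_single = int(round(outlier_spec.frac_single * n_sets))
    n_double = int(round(outlier_spec.frac_double * n_sets))
    chosen = rng.choice(n_sets, size=n_single + n_double, replace=False)
    positions: list[tuple[str, float, str, int]] = []

    col_cache = {c: experiment.condition_samples(*c) for c in conditions}
    for j, set_idx in enumerate(chosen):
        gi, ci = divmod(int(set_idx), len(conditions))
        brix, tissue = conditions[ci]
        ids = col_cache[(brix, tissue)]
        vals = out.values.loc[genes[gi], ids].to_numpy(dtype=float)
        sd = vals.std(ddof=1)
        if sd == 0:
            continue
        k = 1 if j < n_single else 2
        reps = rng.choice(len(ids), size=k, replace=False)
        signs = [rng.choice([-1.0, 1.0])]
        if k == 2:
            signs.append(-signs[0])
        for r, sign in zip(reps, signs):
            vals[r] += sign * outlier_spec.displacement_sd * sd
            rep_idx = int(experiment.design.loc[ids[r], "replicate"])
            positions.append((genes[gi], brix, tissue, rep_idx))
        out.values.loc[genes[gi], ids] = vals
    return out, GroundTruth(outlier_positions=positions)


# ---------------------------------------------------------------------------
# GO annotation
# ---------------------------------------------------------------------------

def simulate_go_annotation(n_genes: int,
                           n_terms: int,
                           planted_terms: Mapping[str, tuple[int, float]],
                           seed: int,
                           significant_set_size: int = 500,
                           term_size_range: tuple[int, int] = (10, 200),
                           genes: Sequence[str] | None = None,
                           significant_set: Sequence[str] | None = None,
                           ) -> tuple[pd.DataFrame, GroundTruth]:
    """Build a gene→term table with terms over-drawn in a designated gene set.

    ``planted_terms`` maps a term id to (term size, fold enrichment); the
    term's members inside the significant set are over-sampled so that the
    in-set count is ``fold x`` the expectation under random annotation.
    Remaining terms are drawn uniformly (fold 1).
    """
    rng = child_rng(seed, "go")
    if genes is None:
        genes = [f"g{i:05d}" for i in range(n_genes)]
    genes = list(genes)
    if len(genes) != n_genes:
        raise ValueError("gene list length mismatch")
    if significant_set is None:
        significant_set = list(rng.choice(genes, size=significant_set_size,
                                          replace=False))
    sig = set(significant_set)
    others = [g for g in genes if g not in sig]
    term_ids = [f"GO:{i:07d}" for i in range(n_terms)]
    unknown = set(planted_terms) - set(term_ids)
    if unknown:
        raise ValueError(f"planted terms outside the term set: {sorted(unknown)}")

    rows = []
    truth_terms: dict[str, float] = {}
    for term in term_ids:
        if term in planted_terms:
            size, fold = planted_terms[term]
            if fold <= 1:
                raise ValueError("planted fold-enrichment must exceed 1")
        else:
            size, fold = int(rng.integers(*term_size_range)), 1.0
        if size > n_genes:
            raise ValueError("term size exceeds number of genes")
        expected_in_set = size * len(sig) / n_genes
        k_in = int(round(min(fold * expected_in_set, min(size, len(sig)))))
        members = list(rng.choice(sorted(sig), size=k_in, replace=False)) + \
            list(rng.choice(others, size=size - k_in, replace=False))
        rows.extend((g, term) for g in members)
        if fold > 1:
            truth_terms[term] = fold
    table = pd.DataFrame(rows, columns=["gene", "term"])
    truth = GroundTruth(enriched_terms=truth_terms,
                        significant_set=list(significant_set))
    return table, truth


# ---------------------------------------------------------------------------
# Probe sequences and alignment hits
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))
HIT_COLUMNS = ["query", "subject", "pident", "length", "mismatch", "gapopen",
               "qstart", "qend", "sstart", "send", "evalue", "bitscore"]


def _mutate(seq: str, n_mut: int, rng: np.random.Generator) -> str:
    if n_mut >= len(seq):
        raise ValueError("mismatch count must be below probe length")
    pos = rng.choice(len(seq), size=n_mut, replace=False)
    out = list(seq)
    for p in pos:
        out[p] = rng.choice([b for b in "ACGT" if b != out[p]])
    return "".join(out)


def simulate_probe_hits(n_genes: int,
                        probes_per_gene: int = 4,
                        mismatch_spec: Sequence[tuple[float, int]] = (
                            (0.05, 1), (0.05, 20)),
                        seed: int = 0,
                        probe_length: int = 60,
                        target_length: int = 300,
                        tm_delta: float = 10.0,
                        ) -> tuple[dict[str, str], dict[str, str],
                                   pd.DataFrame, GroundTruth]:
    """Generate probes, targets and a 12-column alignment-hit table.

    Every gene gets ``probes_per_gene`` perfect-match probes drawn from its
    target sequence.  ``mismatch_spec`` lists (fraction of genes, mismatch
    count) groups: for each affected gene, a probe copy carrying that many
    substitutions is embedded in another gene's target, producing an
    off-target hit.  Truth labels apply the duplex-Tm rule (hit Tm above the
    gene's minimum perfect-match Tm minus ``tm_delta``).

    Returns ``(probes, targets, hits, truth)`` with sequences as id→sequence
    dicts.
    """
    from .probes import compute_tm  # deferred: avoids import cycle at load

    if probes_per_gene < 1:
        raise ValueError("probes_per_gene must be >= 1")
    rng = child_rng(seed, "probes")
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    targets = {g: "".join(rng.choice(_BASES, size=target_length))
               for g in gene_ids}
    probes: dict[str, str] = {}
    pm_tms: dict[str, list[float]] = {g: [] for g in gene_ids}
    rows = []
    step = max(1, (target_length - probe_length) // max(probes_per_gene, 1))
    for g in gene_ids:
        for p in range(probes_per_gene):
            start = p * step
            seq = targets[g][start:start + probe_length]
            pid = f"{g}_p{p + 1}"
            probes[pid] = seq
            pm_tms[g].append(compute_tm(seq, seq))
            rows.append((pid, g, 100.0, probe_length, 0, 0,
                         1, probe_length, start + 1, start + probe_length,
                         0.0, 2 * probe_length))

    truth_labels = {g: False for g in gene_ids}
    for frac, n_mut in mismatch_spec:
        n_aff = int(round(frac * n_genes))
        affected = rng.choice(n_genes, size=n_aff, replace=False)
        for gi in affected:
            g = gene_ids[int(gi)]
            other = gene_ids[int((gi + 1 + rng.integers(n_genes - 1))
                                 % n_genes)]
            pid = f"{g}_p1"
            mutated = _mutate(probes[pid], n_mut, rng)
            # append the mutated copy to the other gene's target so the
            # regions its own probes were drawn from stay intact
            offset = len(targets[other])
            targets[other] = targets[other] + mutated
            identity = 100.0 * (probe_length - n_mut) / probe_length
            rows.append((pid, other, identity, probe_length, n_mut, 0,
                         1, probe_length, offset + 1, offset + probe_length,
                         0.0, 2 * (probe_length - n_mut)))
            if identity > 80.0:  # below the retention rule it can never flag
                tm = compute_tm(probes[pid], mutated)
                threshold = min(pm_tms[g]) - tm_delta
                truth_labels[g] = truth_labels[g] or (tm > threshold)

    hits = pd.DataFrame(rows, columns=HIT_COLUMNS)
    truth = GroundTruth(crosshyb_genes=truth_labels)
    return probes, targets, hits, truth


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


# ---------------------------------------------------------------------------
# Standard addition
# ---------------------------------------------------------------------------

def simulate_standard_addition(true_conc: float,
                               spikes: Sequence[float] = (0.0, 10.0, 25.0, 50.0),
                               ratio_noise_cv: float = 0.02,
                               seed: int = 0,
                               response_slope: float = 0.02,
                               ) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate analyte/internal-standard response ratios under spiking.

    ``ratio_i = b (true_conc + spike_i) (1 + eps_i)`` with
    ``eps_i ~ N(0, ratio_noise_cv^2)``.
    """
    if true_conc < 0:
        raise ValueError("true concentration must be non-negative")
    if ratio_noise_cv < 0:
        raise ValueError("noise CV must be non-negative")
    spikes = np.asarray(sorted(spikes), dtype=float)
    if spikes.size < 2 or np.unique(spikes).size < 2 or (spikes < 0).any():
        raise ValueError("need >= 2 distinct non-negative spike levels")
    rng = child_rng(seed, "quant")
    eps = rng.normal(0.0, ratio_noise_cv, size=spikes.size) \
        if ratio_noise_cv > 0 else np.zeros(spikes.size)
    ratios = response_slope * (true_conc + spikes) * (1.0 + eps)
    table = pd.DataFrame({"spike_ng_L": spikes, "ratio": ratios})
    return table, GroundTruth(true_concentration=float(true_conc))
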