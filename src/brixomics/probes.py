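"""Microarray probe cross-hybridization screening.

Probe-target alignments (a 12-column tabular hit file from an external
aligner) are filtered by a strict >80% identity and >80% coverage rule,
the retained duplexes are scored with a nearest-neighbor thermodynamic
melting temperature, and a hit is called a putative cross-hybridization
when its duplex Tm exceeds the minimum Tm of the probe gene's
perfectly-matching probe set minus a margin (10 °C by default).  A gene is
flagged when any probe of its set cross-hybridizes with another gene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .synthetic import HIT_COLUMNS

R_GAS = 1.987  # cal / (mol K)

# Unified nearest-neighbor parameters for DNA/DNA duplexes
# (dH kcal/mol, dS cal/(mol K)); Watson-Crick stacks in 5'->3' order.
NN_UNIFIED: dict[str, tuple[float, float]] = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
# Duplex initiation at a terminal pair.
INIT_GC = (0.1, -2.8)
INIT_AT = (2.3, 4.1)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _is_complementary(a: str, b: str) -> bool:
    return a.translate(_COMPLEMENT) == b


@dataclass
class ProbeHit:
    """One probe-target alignment with its reconstructed duplex."""

    probe_id: str
    probe_gene: str
    target_gene: str
    identity: float      # percent
    coverage: float      # percent of the probe aligned
    probe_seq: str       # aligned probe fragment, 5'->3'
    target_seq: str      # target fragment in probe orientation; equal base = match

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 100.0 and 0.0 <= self.coverage <= 100.0):
            raise ValueError("identity and coverage must lie in [0, 100]")

    @property
    def mismatch_positions(self) -> list[int]:
        return [i for i, (a, b) in enumerate(zip(self.probe_seq, self.target_seq))
                if a != b]


@dataclass
class CrossHybCall:
    hit: ProbeHit
    duplex_tm: float
    threshold_tm: float
    verdict: bool


# ---------------------------------------------------------------------------
# Melting temperature
# ---------------------------------------------------------------------------

def compute_tm(probe: str,
               target: str | None = None,
               na_molar: float = 0.05,
               strand_conc: float = 1e-7,
               symmetry_factor: float = 4.0,
               mismatch_table: Mapping[str, tuple[float, float]] | None = None,
               ) -> float:
    """Nearest-neighbor duplex melting temperature in °C.

    ``target`` is given in the probe's orientation, so an equal base means a
    Watson-Crick pair and a differing base (or ``-``) a mismatch.  Stacks in
    which either position is mismatched contribute the ``mismatch_table``
    entry for the probe dinucleotide, or nothing by default, which lowers the
    Tm of imperfect duplexes.  ``Tm = dH / (dS' + R ln(C_T / x)) - 273.15``
    with the entropic monovalent-salt correction
    ``dS' = dS + 0.368 (N - 1) ln[Na+]`` applied over the paired region.
    """
    probe = probe.upper()
    if target is None:
        target = probe
    target = target.upper()
    if len(probe) != len(target) or not probe:
        raise ValueError("probe and target must be equal-length and non-empty")
    allowed = set("ACGT-")
    if (set(probe) | set(target)) - allowed:
        raise ValueError("sequences must be DNA (ACGT, '-' for gaps)")
    match = [a == b and a != "-" for a, b in zip(probe, target)]
    idx = [i for i, m in enumerate(match) if m]
    if not idx:
        raise ValueError("duplex has no matched region")
    first, last = idx[0], idx[-1]
    dh, ds = 0.0, 0.0
    n_pairs = 0
    for i in range(first, last):
        n_pairs += 1
        if match[i] and match[i + 1]:
            h, s = NN_UNIFIED[probe[i:i + 2]]
        elif mismatch_table is not None:
            h, s = mismatch_table.get(probe[i:i + 2], (0.0, 0.0))
        else:
            h, s = 0.0, 0.0
        dh += h
        ds += s
    n_pairs += 1  # pairs = stacks + 1 over the trimmed region
    for terminal in (probe[first], probe[last]):
        h, s = INIT_GC if terminal in "GC" else INIT_AT
        dh += h
        ds += s
    ds += 0.368 * (n_pairs - 1) * math.log(na_molar)
    denom = ds + R_GAS * math.log(strand_conc / symmetry_factor)
    if denom >= 0 or dh >= 0:
        raise ValueError("duplex too unstable for a defined Tm")
    return dh * 1000.0 / denom - 273.15


def perfect_match_tms(probes_by_gene: Mapping[str, Mapping[str, str]],
                      **tm_kwargs) -> dict[str, list[float]]:
    """Tm of every probe against its perfect complement, grouped by gene."""
    return {gene: [compute_tm(seq, seq, **tm_kwargs)
                   for seq in probes.values()]
            for gene, probes in probes_by_gene.items()}


# ---------------------------------------------------------------------------
# Hit handling
# ---------------------------------------------------------------------------

def read_hit_table(path: str | Path) -> pd.DataFrame:
    """Read a 12-column tabular alignment file (no header)."""
    return pd.read_csv(path, sep="\t", names=HIT_COLUMNS)


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def build_probe_hits(hits: pd.DataFrame,
                     probes: Mapping[str, str],
                     targets: Mapping[str, str],
                     probe_gene: callable = lambda pid: pid.rsplit("_p", 1)[0],
                     ) -> list[ProbeHit]:
    """Reconstruct aligned duplexes from hit coordinates and sequences.

    Coverage is the aligned fraction of the probe.  Hits on the reverse
    strand (sstart > send) are reverse-complemented into probe orientation.
    """
    out = []
    for row in hits.itertuples(index=False):
        pseq = probes[row.query][row.qstart - 1:row.qend]
        s0, s1 = int(row.sstart), int(row.send)
        if s0 <= s1:
            tseq = targets[row.subject][s0 - 1:s1]
        else:
            tseq = targets[row.subject][s1 - 1:s0]
            tseq = tseq.translate(_COMPLEMENT)[::-1]
        coverage = 100.0 * (row.qend - row.qstart + 1) / len(probes[row.query])
        out.append(ProbeHit(
            probe_id=row.query,
            probe_gene=probe_gene(row.query),
            target_gene=row.subject,
            identity=float(row.pident),
            coverage=coverage,
            probe_seq=pseq,
            target_seq=tseq,
        ))
    return out


def filter_hits(hits: Iterable[ProbeHit],
                min_identity: float = 80.0,
                min_coverage: float = 80.0) -> list[ProbeHit]:
    """Retain hits with identity AND coverage strictly above the thresholds."""
    return [h for h in hits
            if h.identity > min_identity and h.coverage > min_coverage]


def classify_cross_hyb(hits: Iterable[ProbeHit],
                       pm_tms_by_gene: Mapping[str, Sequence[float]],
                       delta: float = 10.0,
                       **tm_kwargs) -> list[CrossHybCall]:
    """Call cross-hybridization per hit against the per-gene Tm threshold.

    The threshold is the minimum perfect-match Tm of the probe gene's probe
    set minus ``delta``; the verdict is strict (Tm must exceed it).  A hit
    whose gene has no perfect-match Tm is an error, not a silent skip.
    """
    calls = []
    for h in hits:
        tms = pm_tms_by_gene.get(h.probe_gene)
        if not tms:
            raise ValueError(
                f"gene {h.probe_gene} has no perfect-match probe Tm")
        threshold = min(tms) - delta
        tm = compute_tm(h.probe_seq, h.target_seq, **tm_kwargs)
        calls.append(CrossHybCall(hit=h, duplex_tm=tm,
                                  threshold_tm=threshold,
                                  verdict=tm > threshold))
    return calls


def flag_genes(calls: Iterable[CrossHybCall]) -> tuple[pd.Series, int]:
    """Flag genes with >= 1 cross-hybridizing probe against another gene."""
    flags: dict[str, bool] = {}
    for c in calls:
        g = c.hit.probe_gene
        flags.setdefault(g, False)
        if c.verdict and c.hit.target_gene != g:
            flags[g] = True
    series = pd.Series(flags, dtype=bool).sort_index()
    return series, int(series.sum())


def calls_to_frame(calls: Iterable[CrossHybCall]) -> pd.DataFrame:
    return pd.DataFrame([{
        "probe": c.hit.probe_id,
        "probe_gene": c.hit.probe_gene,
        "target_gene": c.hit.target_gene,
        "identity": c.hit.identity,
        "coverage": c.hit.coverage,
        "tm": c.duplex_tm,
        "threshold": c.threshold_tm,
        "verdict": c.verdict,
    } for c in calls])
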