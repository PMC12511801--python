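"""Reliability and identifiability of repeated-scan connectivity matrices.

Given scans X_ij (subject i, repeat j), the distance-based intraclass
correlation is

    dICC = 1 − MSD_w / MSD_b,

with MSD_w the mean squared distance over within-subject scan pairs and
MSD_b over between-subject pairs (Frobenius distance by default). dICC
approaches 1 when repeats are far more alike than different subjects, and
0 when scans are exchangeable; values below 0.4 are conventionally flagged
as poor reliability.

Identifiability works on similarities instead: with μ_intra / μ_inter the
mean within/between-subject similarity (mean row-wise Pearson correlation
between matrices) and s the pooled SD of the two similarity samples,

    identifiability = |μ_intra − μ_inter| / s.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np

from surfconn.smoothing import ConnectivityMatrix

__all__ = [
    "ScanCollection",
    "ReliabilityReport",
    "dicc",
    "similarity",
    "reliability_identifiability",
    "DICC_POOR_RELIABILITY",
]

# conventional flag: dICC below this suggests poor reliability
DICC_POOR_RELIABILITY = 0.4


def _as_array(x) -> np.ndarray:
    if isinstance(x, ConnectivityMatrix):
        return x.values
    return np.asarray(x, dtype=np.float64)


@dataclasses.dataclass(frozen=True)
class ScanCollection:
    """Repeated scans per subject: ``scans[i][j]`` is subject i's j-th scan."""

    scans: tuple[tuple[np.ndarray, ...], ...]

    def __init__(self, scans):
        normalized = tuple(tuple(_as_array(s) for s in subject) for subject in scans)
        if len(normalized) < 1:
            raise ValueError("collection must contain at least one subject")
        shapes = {s.shape for subject in normalized for s in subject}
        if len(shapes) != 1:
            raise ValueError("all scans must share one shape")
        object.__setattr__(self, "scans", normalized)

    @property
    def n_subjects(self) -> int:
        return len(self.scans)

    @property
    def repeats(self) -> tuple[int, ...]:
        return tuple(len(s) for s in self.scans)


def _distance(a: np.ndarray, b: np.ndarray, upper_only: bool) -> float:
    d = a - b
    if upper_only:
        iu = np.triu_indices(d.shape[0])
        return float(np.sqrt((d[iu] ** 2).sum()))
    return float(np.linalg.norm(d, "fro"))


def dicc(collection: ScanCollection, *, upper_only: bool = False) -> float:
    """Distance-based ICC, 1 − MSD̂_w / MSD̂_b.

    MSD̂_b averages squared distances over every between-subject scan pair
    (all i1 < i2, all repeat combinations); MSD̂_w over every within-subject
    pair (all j1 < j2 per subject). Frobenius distance on the full matrix
    by default; ``upper_only`` restricts to the upper triangle.
    """
    scans = collection.scans
    n = collection.n_subjects
    if n < 2:
        raise ValueError("dICC needs at least 2 subjects")
    if max(collection.repeats) < 2:
        raise ValueError("dICC needs a subject with at least 2 repeats")
    num_w, cnt_w = 0.0, 0
    for subject in scans:
        for a, b in itertools.combinations(subject, 2):
            num_w += _distance(a, b, upper_only) ** 2
            cnt_w += 1
    num_b, cnt_b = 0.0, 0
    for s1, s2 in itertools.combinations(scans, 2):
        for a in s1:
            for b in s2:
                num_b += _distance(a, b, upper_only) ** 2
                cnt_b += 1
    msd_b = num_b / cnt_b
    if msd_b == 0:
        raise ValueError("between-subject MSD is zero; dICC undefined")
    msd_w = num_w / cnt_w
    return 1.0 - msd_w / msd_b


def similarity(pa, pb) -> float:
    """Mean row-wise Pearson correlation between two matrices.

    Rows with zero variance in either matrix are excluded; an error is
    raised if every row is degenerate.
    """
    a = _as_array(pa)
    b = _as_array(pb)
    if a.shape != b.shape:
        raise ValueError("matrices must have equal shape")
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    na = np.linalg.norm(ac, axis=1)
    nb = np.linalg.norm(bc, axis=1)
    ok = (na > 0) & (nb > 0)
    if not ok.any():
        raise ValueError("all rows are degenerate (zero variance)")
    r = (ac[ok] * bc[ok]).sum(axis=1) / (na[ok] * nb[ok])
    return float(r.mean())


@dataclasses.dataclass(frozen=True)
class ReliabilityReport:
    """dICC, similarity summaries, and identifiability for one collection."""

    dicc: float
    mu_intra: float
    mu_inter: float
    pooled_sd: float
    identifiability: float

    @property
    def poor_reliability(self) -> bool:
        """True when dICC falls below the conventional 0.4 flag."""
        return self.dicc < DICC_POOR_RELIABILITY


def reliability_identifiability(collection: ScanCollection) -> ReliabilityReport:
    """Within/between similarity summaries and identifiability.

    μ_intra averages similarity over within-subject scan pairs, μ_inter
    over between-subject pairs; s is the two-sample pooled standard
    deviation of the similarity samples and identifiability is
    |μ_intra − μ_inter| / s.
    """
    scans = collection.scans
    within = [
        similarity(a, b)
        for subject in scans
        for a, b in itertools.combinations(subject, 2)
    ]
    between = [
        similarity(a, b)
        for s1, s2 in itertools.combinations(scans, 2)
        for a in s1
        for b in s2
    ]
    if not within or not between:
        raise ValueError("need at least one within- and one between-subject pair")
    w = np.asarray(within)
    b = np.asarray(between)
    mu_intra = float(w.mean())
    mu_inter = float(b.mean())
    nw, nb = w.size, b.size
    var_w = float(w.var(ddof=1)) if nw > 1 else 0.0
    var_b = float(b.var(ddof=1)) if nb > 1 else 0.0
    denom = nw + nb - 2
    if denom <= 0:
        raise ValueError("too few similarity pairs for a pooled SD")
    s = float(np.sqrt(((nw - 1) * var_w + (nb - 1) * var_b) / denom))
    if s == 0:
        raise ValueError("pooled SD is zero; identifiability undefined")
    return ReliabilityReport(
        dicc=dicc(collection),
        mu_intra=mu_intra,
        mu_inter=mu_inter,
        pooled_sd=s,
        identifiability=abs(mu_intra - mu_inter) / s,
    )
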