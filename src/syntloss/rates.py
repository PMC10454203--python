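"""Relative evolutionary rate statistics.

Two classical tests over multiple sequence alignments:

* **Tajima's relative rate test** compares, in a (focal, reference,
  outgroup) triplet, the number of sites where only the focal species
  differs (m1) against the number where only the reference differs (m2).
  Under equal rates E[m1] = E[m2]; the statistic (m1 - m2)^2 / (m1 + m2)
  is asymptotically chi-squared with 1 degree of freedom.

* **Two-cluster test**: the difference between the mean outgroup
  distance of cluster A and that of cluster B, standardized by a
  column-bootstrap standard error into a Z statistic (two-sided normal
  test).  Distances default to Jukes-Cantor (JC69).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
GAP_CODE = 255


def encode_alignment_row(seq: str) -> np.ndarray:
    """Encode a nucleotide sequence as uint8 (non-ACGT -> GAP_CODE)."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    lut = np.full(256, GAP_CODE, dtype=np.uint8)
    for c, v in _CODE.items():
        lut[ord(c)] = v
    return lut[arr]


def _as_row(seq) -> np.ndarray:
    if isinstance(seq, np.ndarray):
        return seq.astype(np.uint8, copy=False)
    return encode_alignment_row(str(seq))


@dataclass(frozen=True)
class TripletCounts:
    m1: int          # sites where only the focal species differs
    m2: int          # sites where only the reference differs
    n_used: int      # ungapped columns examined
    chi2: float
    p: float


def tajima_rrt(focal, reference, outgroup) -> TripletCounts:
    """Tajima's relative rate test on a (focal, reference, outgroup) triplet.

    Accepts strings or pre-encoded uint8 rows of equal length.  Columns
    with any gap/ambiguity are excluded; columns where all three states
    differ contribute to neither count.
    """
    f, r, o = _as_row(focal), _as_row(reference), _as_row(outgroup)
    if not (f.size == r.size == o.size):
        raise ValueError("aligned sequences must have equal lengths")
    ok = (f != GAP_CODE) & (r != GAP_CODE) & (o != GAP_CODE)
    f, r, o = f[ok], r[ok], o[ok]
    m1 = int(((f != r) & (r == o)).sum())
    m2 = int(((r != f) & (f == o)).sum())
    if m1 + m2 == 0:
        chi2, p = 0.0, 1.0
    else:
        chi2 = (m1 - m2) ** 2 / (m1 + m2)
        p = float(stats.chi2.sf(chi2, df=1))
    return TripletCounts(m1=m1, m2=m2, n_used=int(ok.sum()), chi2=float(chi2), p=p)


# ------------------------------------------------------------------ distances

def p_distance(a, b) -> float:
    x, y = _as_row(a), _as_row(b)
    if x.size != y.size:
        raise ValueError("aligned sequences must have equal lengths")
    ok = (x != GAP_CODE) & (y != GAP_CODE)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("no comparable columns")
    return float((x[ok] != y[ok]).sum()) / n


def jc69_distance(a, b) -> float:
    """Jukes-Cantor distance d = -(3/4) ln(1 - 4p/3)."""
    p = p_distance(a, b)
    if p >= 0.75:
        raise ValueError(f"JC69 undefined for p-distance {p:.3f} >= 0.75")
    return float(-0.75 * np.log1p(-4.0 * p / 3.0))


def _jc_from_p(p: np.ndarray) -> np.ndarray:
    if np.any(p >= 0.75):
        raise ValueError("JC69 undefined for p-distance >= 0.75")
    return -0.75 * np.log1p(-4.0 * p / 3.0)


@dataclass(frozen=True)
class TwoClusterResult:
    delta: float
    se_boot: float
    z: float
    p: float
    n_boot: int
    seed: int
    n_columns: int


def two_cluster_test(
    alignment: dict[str, object],
    cluster_a: list[str],
    cluster_b: list[str],
    outgroup: str,
    n_boot: int = 1000,
    seed: int = 0,
    model: str = "jc69",
) -> TwoClusterResult:
    """Compare mean outgroup distance of cluster A against cluster B.

    ``delta = mean_A d(sp, outgroup) - mean_B d(sp, outgroup)``; positive
    delta means cluster A evolves faster.  The standard error comes from
    ``n_boot`` column-resampled replicates; complete deletion is applied
    (only columns ungapped in every involved sequence are used).
    """
    a_set, b_set = set(cluster_a), set(cluster_b)
    if not cluster_a or not cluster_b:
        raise ValueError("clusters must be non-empty")
    if a_set & b_set:
        raise ValueError("clusters must be disjoint")
    if outgroup in a_set | b_set:
        raise ValueError("outgroup cannot belong to a cluster")
    species = list(cluster_a) + list(cluster_b) + [outgroup]
    missing = [s for s in species if s not in alignment]
    if missing:
        raise ValueError(f"species missing from alignment: {missing}")
    rows = {s: _as_row(alignment[s]) for s in species}
    lengths = {r.size for r in rows.values()}
    if len(lengths) != 1:
        raise ValueError("aligned sequences must have equal lengths")
    ok = np.ones(lengths.pop(), dtype=bool)
    for r in rows.values():
        ok &= r != GAP_CODE
    n_cols = int(ok.sum())
    if n_cols == 0:
        raise ValueError("no ungapped columns shared by all species")
    out_row = rows[outgroup][ok]
    # per-species mismatch indicators vs the outgroup; bootstrap resamples these
    mismatch = {
        s: (rows[s][ok] != out_row).astype(np.float64)
        for s in list(cluster_a) + list(cluster_b)
    }

    def delta_from(cols: np.ndarray | slice) -> float:
        def mean_dist(group: list[str]) -> float:
            ps = np.array([mismatch[s][cols].mean() for s in group])
            if model == "jc69":
                return float(_jc_from_p(ps).mean())
            return float(ps.mean())

        return mean_dist(list(cluster_a)) - mean_dist(list(cluster_b))

    delta = delta_from(slice(None))
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n_cols, n_cols)
        boots[b] = delta_from(idx)
    se = float(boots.std(ddof=1))
    if se > 0:
        z = delta / se
        p = float(2.0 * stats.norm.sf(abs(z)))
    else:
        z = 0.0 if delta == 0.0 else float(np.sign(delta) * np.inf)
        p = 1.0 if delta == 0.0 else 0.0
    return TwoClusterResult(
        delta=float(delta), se_boot=se, z=float(z), p=p,
        n_boot=n_boot, seed=seed, n_columns=n_cols,
    )


# ------------------------------------------------------------------ simulation

def evolve_jc(ancestor: np.ndarray, branch_length: float, rng: np.random.Generator) -> np.ndarray:
    """Evolve a coded sequence along a branch under JC69.

    ``branch_length`` is in expected substitutions/site; each site stays
    put with probability 1/4 + (3/4) exp(-4d/3), otherwise moves to one
    of the other three states uniformly.
    """
    p_stay = 0.25 + 0.75 * np.exp(-4.0 * branch_length / 3.0)
    out = ancestor.copy()
    move = rng.random(out.size) >= p_stay
    shift = rng.integers(1, 4, size=int(move.sum())).astype(np.uint8)
    out[move] = (out[move] + shift) % 4
    return out


def simulate_triplet(
    n_sites: int,
    focal_branch: float,
    reference_branch: float,
    outgroup_branch: float,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate (focal, reference, outgroup) rows from one root sequence."""
    rng = np.random.default_rng(seed)
    root = rng.integers(0, 4, size=n_sites, dtype=np.uint8)
    focal = evolve_jc(root, focal_branch, rng)
    reference = evolve_jc(root, reference_branch, rng)
    outgroup = evolve_jc(root, outgroup_branch, rng)
    return focal, reference, outgroup


def decode_row(row: np.ndarray) -> str:
    letters = np.frombuffer(b"ACGT", dtype=np.uint8)
    return letters[row].tobytes().decode()
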