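"""Case-only vs all-sample MIC contrast test for pairwise SNP epistasis.

For a SNP pair (g_i, g_j) in a case-control study with n samples of which
n2 are cases, the test statistic is

    delta = |MIC_all - MIC_case| / MIC_all

where MIC_all is computed over all samples and MIC_case over cases only.
Controls are sampled independently of the interaction, so an interaction
that drives disease shows up as a case-specific shift in the pair's
dependence.  The null distribution of delta is obtained by permuting the
phenotype labels (preserving the case count) m times; the p-value is the
fraction of permuted statistics at least as large as the observed one.

Because delta depends on the case subset only through the 3x3 case-stratum
contingency table, a uniform label permutation induces a multivariate
hypergeometric draw of those nine cell counts from the pooled pair table.
The permutation loop samples the counts directly, which is exact and fast.
"""
from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from . import mic as micmod
from .mic import DEFAULT_EXPONENT, mic_counts_3x3

__all__ = [
    "MIC_ALL_EPS",
    "GenotypeMatrix",
    "PhenotypeVector",
    "PairResult",
    "ScanResult",
    "NetworkSummary",
    "DeltaMic",
    "delta_mic",
    "permutation_test",
    "enumerate_pairs",
    "pairwise_scan",
    "filter_significant",
    "network_summary",
]

logger = logging.getLogger(__name__)

#: below this MIC_all the pair carries no interpretable all-sample
#: dependence; delta is defined as 0 and the pair flagged degenerate.
MIC_ALL_EPS = 1e-12

MISSING = -1


@dataclass
class GenotypeMatrix:
    """n x p matrix of minor-allele dosages (0/1/2; -1 marks missing)."""

    values: np.ndarray
    sample_ids: Sequence[str]
    snp_ids: Sequence[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be 2-D (samples x SNPs)")
        n, p = self.values.shape
        if n < 2 or p < 2:
            raise ValueError("need at least 2 samples and 2 SNPs")
        bad = ~np.isin(self.values, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype entries must be 0, 1, 2 or missing (-1)")
        self.sample_ids = list(map(str, self.sample_ids))
        self.snp_ids = list(map(str, self.snp_ids))
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length mismatch")
        if len(self.snp_ids) != p:
            raise ValueError("snp_ids length mismatch")
        if len(set(self.sample_ids)) != n or len(set(self.snp_ids)) != p:
            raise ValueError("sample and SNP identifiers must be unique")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def column(self, snp_id: str) -> np.ndarray:
        return self.values[:, self.snp_ids.index(snp_id)]


@dataclass
class PhenotypeVector:
    """Binary case/control labels aligned 1:1 with genotype rows."""

    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int8).ravel()
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("phenotype labels must be 0 (control) or 1 (case)")

    @property
    def n(self) -> int:
        return self.labels.size

    @property
    def n_cases(self) -> int:
        return int(self.labels.sum())


def _labels(y) -> np.ndarray:
    if isinstance(y, PhenotypeVector):
        return y.labels
    return PhenotypeVector(np.asarray(y)).labels


@dataclass(frozen=True)
class PairResult:
    snp_i: str
    snp_j: str
    mic_all: float
    mic_case: float
    delta: float
    pvalue: float
    m: int
    flag: str = "ok"


@dataclass
class ScanResult:
    pairs: list
    alpha: float
    seed: int
    m: int
    exponent: float
    dropped_snps: list = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            (r.snp_i, r.snp_j, r.mic_all, r.mic_case, r.delta, r.pvalue,
             r.m, r.flag)
            for r in self.pairs
        ]
        return pd.DataFrame(
            rows,
            columns=["snp_i", "snp_j", "mic_all", "mic_case", "delta_mic",
                     "pvalue", "m", "flag"],
        )


class DeltaMic(NamedTuple):
    mic_all: float
    mic_case: float
    delta: float
    degenerate: bool


def _pair_table(g_i, g_j):
    """Pairwise complete-case 3x3 contingency table and the row mask."""
    g_i = np.asarray(g_i).ravel()
    g_j = np.asarray(g_j).ravel()
    if g_i.size != g_j.size:
        raise ValueError("genotype columns must have equal length")
    mask = (g_i >= 0) & (g_j >= 0)
    gi = g_i[mask].astype(np.int64)
    gj = g_j[mask].astype(np.int64)
    table = np.bincount(3 * gi + gj, minlength=9).reshape(3, 3)
    return table, mask


def _mic_from_table(table, exponent):
    n = int(table.sum())
    return float(mic_counts_3x3(table, float(n) ** exponent))


def delta_mic(g_i, g_j, y, exponent=DEFAULT_EXPONENT) -> DeltaMic:
    """The case/all MIC contrast for one SNP pair.

    Rows with a missing genotype in either column are dropped pairwise.
    Returns ``DeltaMic(mic_all, mic_case, delta, degenerate)``; the pair is
    degenerate when MIC_all is numerically zero or either column is
    monomorphic, in which case delta is defined as 0.
    """
    labels = _labels(y)
    table_all, mask = _pair_table(g_i, g_j)
    y_cc = labels[mask]
    if int(y_cc.sum()) < 2:
        raise ValueError("need at least 2 cases among complete-case rows")
    case_table, _ = _pair_table(
        np.asarray(g_i).ravel()[mask][y_cc == 1],
        np.asarray(g_j).ravel()[mask][y_cc == 1],
    )
    monomorphic = (table_all.sum(axis=1) > 0).sum() < 2 or \
                  (table_all.sum(axis=0) > 0).sum() < 2
    mic_all = _mic_from_table(table_all, exponent)
    mic_case = _mic_from_table(case_table, exponent)
    if monomorphic or mic_all <= MIC_ALL_EPS:
        return DeltaMic(mic_all, mic_case, 0.0, True)
    return DeltaMic(mic_all, mic_case, abs(mic_all - mic_case) / mic_all, False)


def permutation_test(g_i, g_j, y, m=1000, seed=0, exponent=DEFAULT_EXPONENT,
                     conservative=False, snp_i="snp_i",
                     snp_j="snp_j") -> PairResult:
    """Permutation p-value for the case/all MIC contrast of one SNP pair.

    The labels are shuffled (case count preserved) ``m`` times; since the
    statistic depends on the shuffle only through the case-stratum cell
    counts, the counts are drawn from the equivalent multivariate
    hypergeometric distribution.  MIC_all is computed once — label
    shuffling cannot change it.  ``p = #{delta_perm >= delta_obs} / m``; with
    ``conservative=True`` the (count+1)/(m+1) variant is reported instead.
    Degenerate pairs (zero all-sample MIC or a monomorphic column) get
    delta 0 and p-value 1.
    """
    if m < 1:
        raise ValueError("permutation count m must be >= 1")
    labels = _labels(y)
    table_all, mask = _pair_table(g_i, g_j)
    y_cc = labels[mask]
    n = int(table_all.sum())
    n2 = int(y_cc.sum())
    if not 0 < n2 < n:
        raise ValueError("phenotype must contain both cases and controls")
    # canonical axis orientation: swapping the two SNP columns transposes
    # the pooled table, which would reorder the hypergeometric categories
    # and perturb last-bit float ties; fixing the orientation (and computing
    # the observed statistic from it) makes the test bit-identical under a
    # swap of the pair.
    case_table, _ = _pair_table(
        np.asarray(g_i).ravel()[mask][y_cc == 1],
        np.asarray(g_j).ravel()[mask][y_cc == 1],
    )
    if tuple(table_all.T.ravel()) < tuple(table_all.ravel()):
        table_all = table_all.T
        case_table = case_table.T
    monomorphic = (table_all.sum(axis=1) > 0).sum() < 2 or \
                  (table_all.sum(axis=0) > 0).sum() < 2
    mic_all = _mic_from_table(table_all, exponent)
    mic_case = _mic_from_table(case_table, exponent)
    if monomorphic or mic_all <= MIC_ALL_EPS:
        return PairResult(snp_i, snp_j, mic_all, mic_case, 0.0, 1.0,
                          m, "degenerate")
    delta_obs = abs(mic_all - mic_case) / mic_all
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_hypergeometric(
        table_all.ravel(), n2, size=m
    ).reshape(m, 3, 3)
    bound_case = float(n2) ** exponent
    mic_case_perm = mic_counts_3x3(draws, bound_case)
    delta_perm = np.abs(mic_all - mic_case_perm) / mic_all
    count = int((delta_perm >= delta_obs).sum())
    pvalue = (count + 1) / (m + 1) if conservative else count / m
    return PairResult(snp_i, snp_j, mic_all, mic_case, delta_obs,
                      float(pvalue), m, "ok")


def enumerate_pairs(snp_ids):
    """All unordered SNP pairs, in deterministic lexicographic-index order."""
    return list(combinations(snp_ids, 2))


def _pair_seed(master_seed: int, snp_i: str, snp_j: str) -> int:
    """Deterministic per-pair seed, symmetric in the two SNP identifiers."""
    a, b = sorted((str(snp_i), str(snp_j)))
    key = f"{master_seed}|{a}|{b}".encode()
    digest = hashlib.blake2b(key, digest_size=8).digest()
    return int.from_bytes(digest, "little") % (2**31)


def pairwise_scan(G: GenotypeMatrix, y, m=1000, alpha=0.005, seed=0,
                  exponent=DEFAULT_EXPONENT, conservative=False) -> ScanResult:
    """Run the permutation test on every unordered SNP pair.

    Monomorphic SNPs are dropped (with a warning) before pairing.  Each
    pair's RNG seed is derived by hashing the master seed with the sorted
    pair of SNP identifiers, so results do not depend on column order or
    evaluation order.
    """
    labels = _labels(y)
    if labels.size != G.n_samples:
        raise ValueError("phenotype length does not match genotype rows")
    keep, dropped = [], []
    for j, sid in enumerate(G.snp_ids):
        col = G.values[:, j]
        observed = col[col >= 0]
        if np.unique(observed).size < 2:
            dropped.append(sid)
        else:
            keep.append(sid)
    if dropped:
        logger.warning("dropping %d monomorphic SNP(s): %s",
                       len(dropped), ", ".join(dropped))
    if len(keep) < 2:
        raise ValueError("fewer than 2 polymorphic SNPs; nothing to pair")
    pairs = enumerate_pairs(keep)
    logger.info("scanning %d SNP pairs", len(pairs))
    results = []
    cols = {sid: G.column(sid) for sid in keep}
    for si, sj in pairs:
        results.append(
            permutation_test(cols[si], cols[sj], labels, m=m,
                             seed=_pair_seed(seed, si, sj),
                             exponent=exponent, conservative=conservative,
                             snp_i=si, snp_j=sj)
        )
    return ScanResult(pairs=results, alpha=alpha, seed=seed, m=m,
                      exponent=exponent, dropped_snps=dropped)


def filter_significant(scan, alpha, gene_map: Optional[dict] = None):
    """Pairs with p-value <= alpha, optionally dropping intra-gene pairs.

    ``gene_map`` maps SNP id -> gene name; SNPs absent from the map are
    treated as singleton genes (logged) and therefore never filtered as
    intra-gene.
    """
    pairs = scan.pairs if isinstance(scan, ScanResult) else list(scan)
    kept = []
    uncovered = set()
    for r in pairs:
        if r.pvalue > alpha:
            continue
        if gene_map is not None:
            gi = gene_map.get(r.snp_i)
            gj = gene_map.get(r.snp_j)
            for sid, g in ((r.snp_i, gi), (r.snp_j, gj)):
                if g is None:
                    uncovered.add(sid)
            if gi is not None and gi == gj:
                continue
        kept.append(r)
    if uncovered:
        logger.info("%d SNP id(s) not in gene map; treated as singleton "
                    "genes", len(uncovered))
    return kept


@dataclass
class NetworkSummary:
    """Degree table and weighted edge list of an epistasis network."""

    nodes: pd.DataFrame      # columns: Id, Degree[, Gene]
    edges: pd.DataFrame      # columns: Source, Target, Weight
    average_degree: float


def network_summary(pairs, min_degree=0, top_k=None,
                    gene_map: Optional[dict] = None) -> NetworkSummary:
    """Summarise significant pairs as a SNP network.

    Edges are weighted by the pair's case-sample MIC; a node's degree is
    its number of incident edges.  ``min_degree`` filters the node table,
    ``top_k`` keeps the k highest-degree nodes.  Average degree is
    2*|edges|/|nodes| over the unfiltered network.
    """
    pairs = list(pairs)
    if not pairs:
        empty_nodes = pd.DataFrame(columns=["Id", "Degree"])
        empty_edges = pd.DataFrame(columns=["Source", "Target", "Weight"])
        return NetworkSummary(empty_nodes, empty_edges, 0.0)
    edges = pd.DataFrame(
        [(r.snp_i, r.snp_j, r.mic_case) for r in pairs],
        columns=["Source", "Target", "Weight"],
    )
    degree = {}
    for r in pairs:
        degree[r.snp_i] = degree.get(r.snp_i, 0) + 1
        degree[r.snp_j] = degree.get(r.snp_j, 0) + 1
    avg = 2.0 * len(pairs) / len(degree)
    nodes = pd.DataFrame(sorted(degree.items(), key=lambda kv: (-kv[1], kv[0])),
                         columns=["Id", "Degree"])
    if gene_map is not None:
        nodes["Gene"] = nodes["Id"].map(lambda s: gene_map.get(s, ""))
    nodes = nodes[nodes["Degree"] >= min_degree]
    if top_k is not None:
        nodes = nodes.head(top_k)
    return NetworkSummary(nodes.reset_index(drop=True), edges, avg)
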