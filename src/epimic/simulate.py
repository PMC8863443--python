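"""Two-locus penetrance disease models and case-control genotype simulation.

A two-locus model is a 3x3 penetrance table f(g_A, g_B) — the probability of
disease given the genotype pair — together with the minor-allele frequency
of each locus.  Genotype frequencies follow Hardy-Weinberg proportions
((1-q)^2, 2q(1-q), q^2), the two loci are independent in the population, and
the implied population prevalence and (broad-sense) heritability are

    K  = sum_g P(g) f(g)
    h2 = sum_g P(g) (f(g) - K)^2 / (K (1 - K)).

Three model families are provided:

* odds-parameterised null models (a flat table and a one-locus marginal
  recessive model) used for type-I-error studies;
* six printed disease models with marginal effects (ME);
* randomly generated *pure and strict* epistasis models (NME): every
  single-locus marginal penetrance equals the prevalence, so the pair
  carries no marginal signal and all of the heritability is interaction.

Case-control datasets are sampled ascertained (balanced by default): the
case stratum draws genotype pairs from P(g) f(g) / K and the control
stratum from P(g) (1 - f(g)) / (1 - K), which is exactly the conditional
distribution induced by drawing disease status Bernoulli(f(g)) and filling
the two quotas.  Non-functional noise SNPs are drawn i.i.d. under HWE,
independent of phenotype.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .epistasis import GenotypeMatrix, PhenotypeVector

__all__ = [
    "PenetranceModel",
    "SimConfig",
    "hwe_genotype_freqs",
    "prevalence_from_penetrance",
    "heritability_from_penetrance",
    "marginal_penetrances",
    "table1_model",
    "table2_model",
    "TABLE2_PRINTED_PREVALENCE",
    "generate_pure_strict_model",
    "sample_dataset",
]


def hwe_genotype_freqs(maf: float):
    """Hardy-Weinberg genotype frequencies (P(0), P(1), P(2)) for one locus."""
    if not 0.0 < maf <= 0.5:
        raise ValueError(f"MAF must lie in (0, 0.5], got {maf}")
    q = float(maf)
    return ((1 - q) ** 2, 2 * q * (1 - q), q * q)


@dataclass
class PenetranceModel:
    """3x3 two-locus penetrance table with per-locus MAFs.

    ``table[a, b]`` is the disease probability for ``a`` copies of the minor
    allele at locus A and ``b`` at locus B.  ``prevalence`` and
    ``heritability`` are computed from the table at construction and always
    recomputable from it.
    """

    table: np.ndarray
    maf_a: float
    maf_b: float
    kind: str = "custom"
    prevalence: float = field(init=False)
    heritability: float = field(init=False)

    def __post_init__(self):
        self.table = np.asarray(self.table, dtype=float).reshape(3, 3)
        if ((self.table < 0) | (self.table > 1)).any():
            raise ValueError("penetrances must lie in [0, 1]")
        hwe_genotype_freqs(self.maf_a)
        hwe_genotype_freqs(self.maf_b)
        self.prevalence = prevalence_from_penetrance(self)
        # degenerate tables (K of 0 or 1) admit no heritability
        if 0.0 < self.prevalence < 1.0:
            self.heritability = heritability_from_penetrance(self)
        else:
            self.heritability = float("nan")

    def genotype_pair_freqs(self) -> np.ndarray:
        """9-cell population frequencies P(g_A) P(g_B) as a 3x3 array."""
        pa = np.array(hwe_genotype_freqs(self.maf_a))
        pb = np.array(hwe_genotype_freqs(self.maf_b))
        return np.outer(pa, pb)

    def to_json(self, path=None) -> str:
        payload = {
            "table": [float(v) for v in self.table.ravel()],
            "maf_a": self.maf_a,
            "maf_b": self.maf_b,
            "prevalence": self.prevalence,
            "heritability": self.heritability,
            "kind": self.kind,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "PenetranceModel":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(np.array(payload["table"]).reshape(3, 3),
                   payload["maf_a"], payload["maf_b"],
                   kind=payload.get("kind", "custom"))


def prevalence_from_penetrance(model: PenetranceModel) -> float:
    """Population disease probability K implied by the table under HWE."""
    w = np.outer(hwe_genotype_freqs(model.maf_a),
                 hwe_genotype_freqs(model.maf_b))
    return float((w * np.asarray(model.table, dtype=float).reshape(3, 3)).sum())


def heritability_from_penetrance(model: PenetranceModel) -> float:
    """Broad-sense heritability of the two-locus model.

    h2 = sum_g P(g) (f(g) - K)^2 / (K (1 - K)).  Raises when the implied
    prevalence is degenerate (0 or 1).
    """
    f = np.asarray(model.table, dtype=float).reshape(3, 3)
    w = np.outer(hwe_genotype_freqs(model.maf_a),
                 hwe_genotype_freqs(model.maf_b))
    k = float((w * f).sum())
    if not 0.0 < k < 1.0:
        raise ValueError(f"prevalence {k} admits no heritability")
    return float((w * (f - k) ** 2).sum() / (k * (1 - k)))


def marginal_penetrances(model: PenetranceModel):
    """Per-locus marginal penetrances: (f_A(0..2), f_B(0..2)).

    f_A(a) = sum_b P(b) f(a, b), and symmetrically for locus B.
    """
    f = np.asarray(model.table, dtype=float).reshape(3, 3)
    pa = np.array(hwe_genotype_freqs(model.maf_a))
    pb = np.array(hwe_genotype_freqs(model.maf_b))
    return f @ pb, pa @ f


def table1_model(kind: str, gamma: float = 1.0, theta: float = 5.0,
                 maf: float = 0.2) -> PenetranceModel:
    """Odds-parameterised null models without any interaction term.

    ``no_effect``: every cell has odds gamma.  ``marginal_recessive``: the
    homozygous-minor row of locus B has odds gamma*(1+theta), all other
    cells gamma.  Odds o convert to penetrance f = o / (1 + o); with
    gamma=1 the baseline penetrance is 0.5.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if theta < 0:
        raise ValueError("theta must be non-negative")
    odds = np.full((3, 3), gamma)
    if kind == "marginal_recessive":
        odds[2, :] = gamma * (1 + theta)
    elif kind != "no_effect":
        raise ValueError(f"unknown null-model kind {kind!r}")
    return PenetranceModel(odds / (1 + odds), maf, maf, kind=f"null:{kind}")


# Six disease models with marginal effects: penetrance rows in genotype-pair
# order (AABB, AABb, AAbb, AaBB, AaBb, Aabb, aaBB, aaBb, aabb), with the
# MAF shared by both loci and the printed population prevalence.
_TABLE2 = {
    1: ((0.061, 0.017, 0.017, 0.017, 0.136, 0.136, 0.017, 0.136, 0.136),
        0.1, 0.050),
    2: ((0.060, 0.021, 0.021, 0.021, 0.116, 0.116, 0.021, 0.116, 0.116),
        0.1, 0.050),
    3: ((0.030, 0.080, 0.090, 0.090, 0.010, 0.010, 0.070, 0.040, 0.000),
        0.1, 0.046),
    4: ((0.030, 0.010, 0.020, 0.010, 0.090, 0.050, 0.020, 0.050, 0.070),
        0.1, 0.026),
    5: ((0.020, 0.005, 0.020, 0.007, 0.070, 0.001, 0.003, 0.080, 0.090),
        0.1, 0.017),
    6: ((0.044, 0.066, 0.073, 0.069, 0.021, 0.007, 0.042, 0.073, 0.054),
        0.2, 0.052),
}

#: printed population prevalence of each ME model, for cross-checks.
TABLE2_PRINTED_PREVALENCE = {k: v[2] for k, v in _TABLE2.items()}


def table2_model(index: int) -> PenetranceModel:
    """One of the six published disease models with marginal effects."""
    if index not in _TABLE2:
        raise ValueError(f"ME model index must be 1..6, got {index}")
    row, maf, _ = _TABLE2[index]
    return PenetranceModel(np.array(row).reshape(3, 3), maf, maf,
                           kind=f"me:{index}")


def generate_pure_strict_model(h_target: float, maf: float, prevalence: float,
                               seed: Optional[int] = None,
                               max_tries: int = 1000) -> PenetranceModel:
    """Random pure/strict (no-marginal-effect) epistasis model.

    Draws a Gaussian 3x3 deviation table, projects it onto the affine
    constraint set {all six marginal penetrances equal the prevalence} by
    HWE-weighted double centering, rescales the deviations so the
    heritability hits ``h_target`` exactly, and accepts the candidate when
    every cell lands in [0, 1].  Deterministic given ``seed``; raises when
    no candidate is accepted within ``max_tries`` (infeasible parameter
    triple).
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must lie in (0, 1)")
    if h_target < 0:
        raise ValueError("heritability target must be non-negative")
    if max_tries < 1:
        raise ValueError("max_tries must be >= 1")
    k = float(prevalence)
    if h_target == 0.0:
        return PenetranceModel(np.full((3, 3), k), maf, maf,
                               kind="pure_strict")
    pa = np.array(hwe_genotype_freqs(maf))
    pb = pa
    w = np.outer(pa, pb)
    target_var = h_target * k * (1 - k)
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        e = rng.normal(size=(3, 3))
        # HWE-weighted double centering zeroes every weighted row and
        # column mean, i.e. projects onto equal-marginal deviations.
        row_mean = (e * pb).sum(axis=1, keepdims=True)
        col_mean = (pa[:, None] * e).sum(axis=0, keepdims=True)
        total = float((w * e).sum())
        e = e - row_mean - col_mean + total
        var = float((w * e * e).sum())
        if var < 1e-12:
            continue
        f = k + e * np.sqrt(target_var / var)
        if ((f >= 0.0) & (f <= 1.0)).all():
            return PenetranceModel(f, maf, maf, kind="pure_strict")
    raise ValueError(
        f"no pure/strict table found for (h2={h_target}, maf={maf}, "
        f"K={prevalence}) within {max_tries} tries"
    )


@dataclass
class SimConfig:
    """Configuration of one simulated case-control dataset.

    The first two SNP columns ("P1", "P2") are the functional pair governed
    by the penetrance model; the remaining ``p_total - 2`` noise SNPs
    ("N1", ...) are drawn i.i.d. under HWE at ``noise_maf`` (defaults to the
    model's locus-A MAF), independent of phenotype.
    """

    model: PenetranceModel
    n: int = 4000
    balanced: bool = True
    p_total: int = 10
    noise_maf: Optional[float] = None
    seed: Optional[int] = None

    def __post_init__(self):
        if self.p_total < 2:
            raise ValueError("p_total must be >= 2 (the functional pair)")
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.balanced and self.n % 2:
            raise ValueError("balanced designs need an even sample size")


FUNCTIONAL_IDS = ("P1", "P2")


def sample_dataset(config: SimConfig):
    """Draw one case-control dataset from a two-locus penetrance model.

    Returns ``(GenotypeMatrix, PhenotypeVector)``.  Balanced designs fill
    exactly n/2 case and n/2 control slots; the stratum genotype-pair
    distributions are the Bayes conditionals P(g) f(g) / K and
    P(g) (1 - f(g)) / (1 - K).  Fully reproducible from ``config.seed``.
    """
    model = config.model
    rng = np.random.default_rng(config.seed)
    w = model.genotype_pair_freqs().ravel()
    f = model.table.ravel()
    k = model.prevalence
    if config.balanced:
        n_cases = config.n // 2
        n_controls = config.n - n_cases
        if k <= 0 or not np.any(w * f > 0):
            raise ValueError("penetrance table admits no cases; "
                             "case quota unfillable")
        if k >= 1 or not np.any(w * (1 - f) > 0):
            raise ValueError("penetrance table admits no controls; "
                             "control quota unfillable")
        p_case = w * f / (w * f).sum()
        p_ctrl = w * (1 - f) / (w * (1 - f)).sum()
        cells = np.concatenate([
            rng.choice(9, size=n_cases, p=p_case),
            rng.choice(9, size=n_controls, p=p_ctrl),
        ])
        labels = np.concatenate([np.ones(n_cases, dtype=np.int8),
                                 np.zeros(n_controls, dtype=np.int8)])
        order = rng.permutation(config.n)
        cells, labels = cells[order], labels[order]
    else:
        cells = rng.choice(9, size=config.n, p=w / w.sum())
        labels = (rng.random(config.n) < f[cells]).astype(np.int8)
    g_a, g_b = np.divmod(cells, 3)
    columns = [g_a.astype(np.int8), g_b.astype(np.int8)]
    snp_ids = list(FUNCTIONAL_IDS)
    noise_maf = config.noise_maf if config.noise_maf is not None else model.maf_a
    for j in range(config.p_total - 2):
        # HWE genotype at MAF q is Binomial(2, q) minor-allele copies.
        columns.append(rng.binomial(2, noise_maf,
                                    size=config.n).astype(np.int8))
        snp_ids.append(f"N{j + 1}")
    values = np.column_stack(columns)
    sample_ids = [f"S{i + 1}" for i in range(config.n)]
    return (GenotypeMatrix(values, sample_ids, snp_ids),
            PhenotypeVector(labels))
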