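"""Per-repertoire summary statistics.

All logarithms are base 2: Shannon diversity is reported in bits and
evenness is H'/log2(S), so clonality = 1 - evenness lives on [0, 1] with
1 for a monoclonal sample and 0 for a perfectly even one. Simpson
diversity is 1 - sum(p^2) by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import EmptyRepertoireError, LocusError, ValidationError
from .io import Repertoire

_SUM_TOL = 1e-9


class RawRepertoireWarning(UserWarning):
    """Metric computed on a repertoire that was never depth-normalized."""


@dataclass
class RepertoireMetrics:
    """Bundle of single-repertoire statistics (one row of the metrics table)."""

    clonality: float
    shannon_bits: float
    simpson_diversity: float
    richness: int
    evenness: float
    mean_cdr3_len_aa: float | None
    shm_fraction: float | None
    mean_pgen: float | None
    public_fraction: float | None


def _validate_probs(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("probability vector must be 1-D and non-empty")
    if np.any(p <= 0):
        raise ValidationError("probability vector entries must be > 0")
    if abs(p.sum() - 1.0) > _SUM_TOL:
        raise ValidationError(f"probability vector sums to {p.sum()!r}, not 1")
    return p


def clone_frequencies(rep: Repertoire) -> np.ndarray:
    """Read-frequency vector p_i = read_count_i / total_reads.

    Ordered by descending read count, ties broken by cdr3_nt.
    """
    if rep.richness == 0:
        raise EmptyRepertoireError(f"repertoire {rep.subject_id} has no clonotypes")
    counts = np.array([c.read_count for c in rep.sorted_clonotypes()], dtype=float)
    return counts / counts.sum()


def shannon_diversity(p) -> float:
    """Shannon diversity H' = -sum(p * log2 p), in bits."""
    p = _validate_probs(p)
    return float(-(p * np.log2(p)).sum())


def simpson_diversity(p, as_concentration: bool = False) -> float:
    """Simpson diversity 1 - sum(p^2); the concentration sum(p^2) via flag."""
    p = _validate_probs(p)
    conc = float((p * p).sum())
    return conc if as_concentration else 1.0 - conc


def clonality(p) -> float:
    """1 minus Pielou's evenness J = H'/log2(S).

    Defined as 1.0 for a single-clone distribution (the S -> 1 limit:
    a sample containing only one clone is maximally clonal).
    """
    p = _validate_probs(p)
    s = p.size
    if s == 1:
        return 1.0
    return 1.0 - shannon_diversity(p) / np.log2(s)


def evenness(p) -> float:
    """Pielou's evenness J = H'/log2(S); 0.0 for a single clone."""
    p = _validate_probs(p)
    return 1.0 - clonality(p)


def richness(rep: Repertoire) -> int:
    """Number of distinct CDR3-nt clonotypes (S).

    Comparable across subjects only at a fixed read depth; a warning is
    emitted for raw (never normalized) repertoires.
    """
    if rep.normalized_to is None and rep.richness > 0:
        warnings.warn(
            f"richness of {rep.subject_id} computed on a raw repertoire; "
            "normalize to a common depth for cross-subject comparison",
            RawRepertoireWarning,
            stacklevel=2,
        )
    return rep.richness


def mean_cdr3_length(rep: Repertoire, weighting: str = "clonotype") -> float:
    """Mean CDR3 amino-acid length.

    ``clonotype`` weighting averages over unique clonotypes; ``read``
    weights each clonotype by its read count. Clonotypes without an
    amino-acid translation are skipped.
    """
    if weighting not in ("clonotype", "read"):
        raise ValidationError(f"unknown weighting {weighting!r}")
    lengths, weights = [], []
    for clone in rep.sorted_clonotypes():
        if clone.cdr3_aa:
            lengths.append(len(clone.cdr3_aa))
            weights.append(clone.read_count if weighting == "read" else 1)
    if not lengths:
        raise EmptyRepertoireError(
            f"repertoire {rep.subject_id} has no translatable clonotypes"
        )
    return float(np.average(lengths, weights=weights))


def shm_fraction(
    rep: Repertoire,
    identity_threshold_pct: float = 98.0,
    weighting: str = "clonotype",
) -> float:
    """Fraction of IGH clonotypes somatically hypermutated.

    A clonotype counts as mutated when its V-segment germline identity is
    strictly below ``identity_threshold_pct`` (a clone at exactly the
    threshold is unmutated). Denominator is unique clonotypes by default;
    ``weighting="read"`` weights by read count.
    """
    if rep.locus != "IGH":
        raise LocusError(
            f"somatic hypermutation is defined for IGH, repertoire is {rep.locus}"
        )
    if weighting not in ("clonotype", "read"):
        raise ValidationError(f"unknown weighting {weighting!r}")
    missing = [c.cdr3_nt for c in rep.clonotypes.values() if c.v_identity_pct is None]
    if missing:
        raise ValidationError(
            f"v_identity_pct missing for clonotypes: {', '.join(sorted(missing))}"
        )
    if rep.richness == 0:
        raise EmptyRepertoireError(f"repertoire {rep.subject_id} has no clonotypes")
    mutated, total = 0, 0
    for clone in rep.clonotypes.values():
        w = clone.read_count if weighting == "read" else 1
        total += w
        if clone.v_identity_pct < identity_threshold_pct:
            mutated += w
    return mutated / total


@dataclass
class VUsageMatrix:
    """Per-subject V-gene frequency matrix; rows sum to 1."""

    subjects: list[str]
    v_genes: list[str]
    frequencies: np.ndarray

    def __post_init__(self):
        freq = np.asarray(self.frequencies, dtype=float)
        if freq.shape != (len(self.subjects), len(self.v_genes)):
            raise ValidationError("frequency matrix shape mismatch")
        if np.any(freq < 0):
            raise ValidationError("frequencies must be non-negative")
        if not np.allclose(freq.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError("rows of the usage matrix must sum to 1")
        self.frequencies = freq


def v_usage(reps, weighting: str = "clonotype") -> VUsageMatrix:
    """V-gene usage frequencies over the union of observed genes.

    Genes absent from a subject get frequency 0; row order follows the
    input, column order is lexicographic.
    """
    reps = list(reps)
    if not reps:
        raise ValidationError("at least one repertoire required")
    if weighting not in ("clonotype", "read"):
        raise ValidationError(f"unknown weighting {weighting!r}")
    genes = sorted({c.v_gene for rep in reps for c in rep.clonotypes.values()})
    col = {g: i for i, g in enumerate(genes)}
    freq = np.zeros((len(reps), len(genes)))
    for i, rep in enumerate(reps):
        if rep.richness == 0:
            raise EmptyRepertoireError(f"repertoire {rep.subject_id} has no clonotypes")
        for clone in rep.clonotypes.values():
            w = clone.read_count if weighting == "read" else 1
            freq[i, col[clone.v_gene]] += w
        freq[i] /= freq[i].sum()
    return VUsageMatrix([rep.subject_id for rep in reps], genes, freq)


def usage_pca(m: VUsageMatrix, n_components: int = 2):
    """Column-centered PCA of a usage matrix.

    Returns ``(scores, loadings, explained_variance_ratio)`` where
    ``scores`` is subjects x components, ``loadings`` genes x components
    (orthonormal), and the explained-variance ratios are non-increasing.
    The gene with the largest absolute loading on each component carries
    a positive sign, fixing the rotation deterministically.
    """
    x = np.asarray(m.frequencies, dtype=float)
    n = x.shape[0]
    if n < 2:
        raise ValidationError("PCA requires at least 2 subjects")
    if n_components > min(x.shape):
        raise ValidationError(
            f"n_components={n_components} exceeds min matrix dimension {min(x.shape)}"
        )
    centered = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    # deterministic sign: largest-|loading| entry of each component positive
    for k in range(vt.shape[0]):
        pivot = np.argmax(np.abs(vt[k]))
        if vt[k, pivot] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    var = s**2 / (n - 1)
    total = var.sum()
    ratio = var / total if total > 0 else np.zeros_like(var)
    scores = (u * s)[:, :n_components]
    loadings = vt[:n_components].T
    return scores, loadings, ratio[:n_components]


def repertoire_metrics(
    rep: Repertoire,
    pgen_model=None,
    public_threshold: float = 1e-9,
) -> RepertoireMetrics:
    """Compute the full single-repertoire statistic bundle.

    Pgen-derived fields (``mean_pgen``, the unweighted mean over
    clonotypes, and ``public_fraction``, the fraction of clonotypes with
    pgen strictly above ``public_threshold``) are filled when a
    generative model is supplied or every clonotype already carries a
    pgen annotation; otherwise they are ``None``. ``shm_fraction`` is
    computed for IGH repertoires only, ``mean_cdr3_len_aa`` only when at
    least one clonotype is translatable.
    """
    p = clone_frequencies(rep)

    if pgen_model is not None:
        from .pgen import annotate_pgen

        rep = annotate_pgen(rep, pgen_model)

    pgens = [c.pgen for c in rep.clonotypes.values()]
    if all(v is not None for v in pgens):
        mean_pgen = float(np.mean(pgens))
        public_fraction = float(np.mean([v > public_threshold for v in pgens]))
    else:
        mean_pgen = None
        public_fraction = None

    try:
        mean_len = mean_cdr3_length(rep)
    except EmptyRepertoireError:
        mean_len = None

    shm = None
    if rep.locus == "IGH":
        shm = shm_fraction(rep)

    return RepertoireMetrics(
        clonality=clonality(p),
        shannon_bits=shannon_diversity(p),
        simpson_diversity=simpson_diversity(p),
        richness=rep.richness,
        evenness=evenness(p),
        mean_cdr3_len_aa=mean_len,
        shm_fraction=shm,
        mean_pgen=mean_pgen,
        public_fraction=public_fraction,
    )
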