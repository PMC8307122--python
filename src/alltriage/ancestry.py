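"""Genetic-ancestry placement by classical multidimensional scaling.

Cohort genotypes are intersected with a list of common sites, pairwise
genetic distances are computed as 1 - IBS (identity by state: the mean
allele-sharing fraction over pairwise-complete loci), the distance
matrix is embedded with classical (Torgerson) MDS, and each query
sample is assigned the reference population whose centroid is nearest
in the first two MDS dimensions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.linalg

from .model import AnnotatedVariant, TriageError, VariantKey

logger = logging.getLogger(__name__)


@dataclass
class GenotypePanel:
    """Samples x loci dosage matrix (0/1/2, NaN = missing).

    ``populations[i]`` is the reference-population label of sample i, or
    None for a query sample awaiting assignment.
    """

    samples: List[str]
    populations: List[Optional[str]]
    loci: List[VariantKey]
    dosages: np.ndarray  # float, shape (n_samples, n_loci), NaN missing

    def __post_init__(self) -> None:
        if self.dosages.shape != (len(self.samples), len(self.loci)):
            raise TriageError("dosage matrix dimensions do not match sample/locus lists")
        if len(self.populations) != len(self.samples):
            raise TriageError("one population label (or None) required per sample")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise TriageError("dosages must be 0, 1, 2 or missing")

    @classmethod
    def from_variants(cls, variants: Sequence[AnnotatedVariant]) -> "GenotypePanel":
        """Panel from VCF-derived variants (all samples unlabeled queries)."""
        samples: List[str] = []
        for v in variants:
            for s in v.sample_genotypes:
                if s not in samples:
                    samples.append(s)
        loci = [v.key for v in variants]
        dosages = np.full((len(samples), len(loci)), np.nan)
        for j, v in enumerate(variants):
            for i, s in enumerate(samples):
                d = v.sample_genotypes.get(s)
                if d is not None:
                    dosages[i, j] = d
        return cls(samples=samples, populations=[None] * len(samples), loci=loci, dosages=dosages)

    @classmethod
    def concat(cls, a: "GenotypePanel", b: "GenotypePanel") -> "GenotypePanel":
        """Stack two panels over the intersection of their loci."""
        common = [k for k in a.loci if k in set(b.loci)]
        if not common:
            raise TriageError("panels share no loci")
        ia = [a.loci.index(k) for k in common]
        ib = [b.loci.index(k) for k in common]
        return cls(
            samples=a.samples + b.samples,
            populations=a.populations + b.populations,
            loci=common,
            dosages=np.vstack([a.dosages[:, ia], b.dosages[:, ib]]),
        )

    def to_tsv(self, path: str | Path) -> None:
        cols = ["sample", "population"] + [f"{c}:{p}:{r}:{al}" for c, p, r, al in self.loci]
        rows = []
        for i, s in enumerate(self.samples):
            row = [s, self.populations[i] or ""]
            row += ["" if np.isnan(d) else str(int(d)) for d in self.dosages[i]]
            rows.append(row)
        pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenotypePanel":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        if df.columns[:2].tolist() != ["sample", "population"]:
            raise TriageError(f"{path}: panel must start with 'sample' and 'population' columns")
        loci = []
        for col in df.columns[2:]:
            c, p, r, al = col.split(":")
            loci.append((c, int(p), r, al))
        dosages = np.full((len(df), len(loci)), np.nan)
        for j, col in enumerate(df.columns[2:]):
            v = df[col].to_numpy()
            mask = v != ""
            dosages[mask, j] = v[mask].astype(float)
        pops = [p if p else None for p in df["population"]]
        return cls(samples=df["sample"].tolist(), populations=pops, loci=loci, dosages=dosages)


def intersect_common_sites(panel: GenotypePanel, common_sites: pd.DataFrame) -> GenotypePanel:
    """Restrict a panel to loci present in the common-sites catalogue
    (exact allele match), preserving locus order."""
    common = {
        (r.chrom, r.pos, r.ref, r.alt) for r in common_sites.itertuples(index=False)
    }
    idx = [j for j, k in enumerate(panel.loci) if k in common]
    if not idx:
        raise TriageError(
            "no panel locus matches the common-sites list; the locus sets "
            "(or their chromosome naming) are probably mismatched"
        )
    return GenotypePanel(
        samples=list(panel.samples),
        populations=list(panel.populations),
        loci=[panel.loci[j] for j in idx],
        dosages=panel.dosages[:, idx],
    )


def genotype_distance_matrix(panel: GenotypePanel) -> np.ndarray:
    """Pairwise genetic distance d = 1 - IBS over pairwise-complete loci.

    IBS(i, j) = mean over loci typed in both samples of
    (2 - |dosage_i - dosage_j|) / 2, so d is in [0, 1], zero on the
    diagonal and symmetric. A sample pair with no pairwise-complete
    locus is an error.
    """
    X = panel.dosages
    n = X.shape[0]
    if n < 2 or X.shape[1] < 1:
        raise TriageError("distance matrix needs >= 2 samples and >= 1 locus")
    D = np.zeros((n, n))
    present = ~np.isnan(X)
    for i in range(n):
        for j in range(i + 1, n):
            both = present[i] & present[j]
            if not both.any():
                raise TriageError(
                    f"samples {panel.samples[i]!r} and {panel.samples[j]!r} share "
                    "no pairwise-complete locus"
                )
            sim = (2.0 - np.abs(X[i, both] - X[j, both])) / 2.0
            D[i, j] = D[j, i] = 1.0 - sim.mean()
    return D


@dataclass
class MdsResult:
    """Embedding coordinates plus per-query population assignments."""

    samples: List[str]
    coordinates: np.ndarray  # (n_samples, k)
    eigenvalues: np.ndarray  # leading k values, descending
    assigned_population: Dict[str, str]
    centroid_distances: Optional[pd.DataFrame] = None
    ambiguous: Optional[Dict[str, bool]] = None


def classical_mds(distances: np.ndarray, k: int = 2) -> Tuple[np.ndarray, np.ndarray]:
    """Classical (Torgerson) MDS of a distance matrix.

    Double-centers the squared distances, eigendecomposes, and scales
    the top-k eigenvectors by the square roots of their eigenvalues.
    Negative eigenvalues (non-Euclidean distances) are truncated at zero
    with a warning. Returns (coordinates, leading eigenvalues).
    """
    D = np.asarray(distances, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise TriageError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise TriageError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-10):
        raise TriageError("distance matrix must have a zero diagonal")
    n = D.shape[0]
    k = min(k, n)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    # eigh returns ascending order; take the top k
    w, V = scipy.linalg.eigh(B)
    order = np.argsort(w)[::-1][:k]
    lam, vec = w[order], V[:, order]
    if (lam < -1e-10).any():
        logger.warning(
            "distance matrix is non-Euclidean: truncating %d negative eigenvalue(s) at zero",
            int((lam < -1e-10).sum()),
        )
    lam = np.clip(lam, 0.0, None)
    coords = vec * np.sqrt(lam)
    # deterministic sign convention: largest-magnitude loading positive
    for d in range(coords.shape[1]):
        col = coords[:, d]
        if col.any():
            if col[np.argmax(np.abs(col))] < 0:
                coords[:, d] = -col
    return coords, lam


def assign_population(
    coordinates: np.ndarray,
    samples: Sequence[str],
    populations: Sequence[Optional[str]],
) -> Tuple[Dict[str, str], pd.DataFrame, Dict[str, bool]]:
    """Nearest-centroid population assignment in the embedding.

    Centroids are the mean coordinates of the labeled reference samples
    of each population; each unlabeled query gets the label of the
    nearest centroid. Exact ties break lexicographically by label and
    are flagged ambiguous.
    """
    labels = sorted({p for p in populations if p is not None})
    if not labels:
        raise TriageError("no labeled reference samples to assign against")
    pops = np.array([p if p is not None else "" for p in populations])
    centroids = {
        lab: coordinates[pops == lab].mean(axis=0) for lab in labels
    }
    queries = [i for i, p in enumerate(populations) if p is None]
    dist_rows, assigned, ambiguous = [], {}, {}
    for i in queries:
        d = {lab: float(np.linalg.norm(coordinates[i] - centroids[lab])) for lab in labels}
        best = min(labels, key=lambda lab: (d[lab], lab))
        tied = [lab for lab in labels if np.isclose(d[lab], d[best])]
        assigned[samples[i]] = best
        ambiguous[samples[i]] = len(tied) > 1
        dist_rows.append({"sample": samples[i], **d})
    dist_df = pd.DataFrame(dist_rows, columns=["sample"] + labels)
    return assigned, dist_df, ambiguous


def run_ancestry(
    panel: GenotypePanel,
    common_sites: Optional[pd.DataFrame] = None,
    k: int = 2,
) -> MdsResult:
    """End-to-end placement: intersect common sites (if given), embed,
    and assign each unlabeled sample a reference population."""
    if common_sites is not None:
        panel = intersect_common_sites(panel, common_sites)
    D = genotype_distance_matrix(panel)
    coords, lam = classical_mds(D, k=k)
    has_refs = any(p is not None for p in panel.populations)
    has_queries = any(p is None for p in panel.populations)
    if has_refs and has_queries:
        assigned, dist_df, ambiguous = assign_population(coords, panel.samples, panel.populations)
    else:
        assigned, dist_df, ambiguous = {}, None, {}
    return MdsResult(
        samples=list(panel.samples), coordinates=coords, eigenvalues=lam,
        assigned_population=assigned, centroid_distances=dist_df, ambiguous=ambiguous,
    )
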