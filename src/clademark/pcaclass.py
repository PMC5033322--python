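"""Single-marker PCA classification with 95% confidence ellipses.

The distances from each strain's copy of one marker gene to every
reference organism's copy form the variable set; a centred (not scaled)
PCA projects strains onto PC1/PC2, each species with >= 3 labelled
members gets a normal-theory confidence ellipse
{x : (x - mu)' Sigma^-1 (x - mu) <= chi2_2(level)} over its scores, and a
strain is called

* the enclosing class when it falls inside exactly one ellipse,
* the Mahalanobis-nearest class (flagged ambiguous) when inside several,
* *outclass* when inside none — the signature of a species not
  represented among the references.

The default workflow refits the PCA jointly on references plus new
strains; a fixed-model projection via stored means/loadings is available
for streaming use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .coregenome import GeneFamily
from .mlsa import Alignment
from .markerrank import _family_alignment
from .mlsa import genetic_distance

__all__ = [
    "PcaModel",
    "ClassEllipse",
    "ClassCall",
    "marker_distance_table",
    "fit_marker_pca",
    "class_ellipses",
    "classify_strains",
]


@dataclass
class PcaModel:
    variable_ids: list[str]
    means: np.ndarray
    loadings: np.ndarray  # V x C, orthonormal columns
    explained_variance_ratio: np.ndarray
    scores: pd.DataFrame  # fitted strains x components
    degenerate: bool = False

    def project(self, X: np.ndarray) -> np.ndarray:
        return (X - self.means) @ self.loadings


@dataclass
class ClassEllipse:
    label: str
    center: np.ndarray  # (PC1, PC2)
    covariance: np.ndarray  # 2x2
    level: float
    n_members: int
    ridged: bool = False

    @property
    def radius2(self) -> float:
        return float(chi2.ppf(self.level, df=2))

    def mahalanobis2(self, xy: np.ndarray) -> float:
        diff = np.asarray(xy, dtype=float) - self.center
        return float(diff @ np.linalg.solve(self.covariance, diff))

    def contains(self, xy: np.ndarray) -> bool:
        return self.mahalanobis2(xy) <= self.radius2


@dataclass
class ClassCall:
    strain_id: str
    call: str  # class label or "outclass"
    mahalanobis: dict[str, float]
    inside: list[str]
    ambiguous: bool = False


def marker_distance_table(
    gene: GeneFamily | Alignment,
    organisms: list[str],
    strains: list[str],
    model: str = "k80",
) -> pd.DataFrame:
    """Strains x organisms distance table for one marker gene.

    Strains lacking the marker are dropped (flagged by their absence from
    the index).
    """
    aln = _family_alignment(gene, [])
    present = set(aln.ids)
    fitted = [s for s in strains if s in present]
    orgs = [o for o in organisms if o in present]
    if not orgs:
        raise ValueError("no reference organism carries the marker")
    needed = list(dict.fromkeys(fitted + orgs))
    dm = genetic_distance(
        Alignment(
            ids=needed,
            rows=[aln.rows[aln.ids.index(s)] for s in needed],
            family_id=aln.family_id,
        ),
        model=model,
    )
    data = {o: [dm.value(s, o) for s in fitted] for o in orgs}
    return pd.DataFrame(data, index=fitted)


def fit_marker_pca(
    gene: GeneFamily | Alignment | pd.DataFrame,
    organisms: list[str],
    strains: list[str],
    model: str = "k80",
    scale: bool = False,
) -> PcaModel:
    """Centred PCA of the marker's distance variables over ``strains``.

    Deterministic sign convention: within each component the
    largest-magnitude loading is positive.  A ``pd.DataFrame`` may be
    passed directly as a precomputed distance table.
    """
    if isinstance(gene, pd.DataFrame):
        table = gene.loc[[s for s in strains if s in gene.index]]
    else:
        table = marker_distance_table(gene, organisms, strains, model=model)
    if table.shape[0] < 3:
        raise ValueError("need >= 3 strains carrying the marker")
    X = table.values.astype(float)
    means = X.mean(axis=0)
    Xc = X - means
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
        means = means  # scaling folded into Xc only; project() assumes no scale
    cov = np.cov(Xc, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0.0, None)
    total = evals.sum()
    degenerate = not np.isfinite(total) or total <= 0
    ratio = evals / total if not degenerate else np.zeros_like(evals)
    # sign convention
    for c in range(evecs.shape[1]):
        i = np.argmax(np.abs(evecs[:, c]))
        if evecs[i, c] < 0:
            evecs[:, c] = -evecs[:, c]
    scores = Xc @ evecs
    comp_names = [f"PC{i + 1}" for i in range(evecs.shape[1])]
    return PcaModel(
        variable_ids=list(table.columns),
        means=means,
        loadings=evecs,
        explained_variance_ratio=ratio,
        scores=pd.DataFrame(scores, index=table.index, columns=comp_names),
        degenerate=degenerate,
    )


def class_ellipses(
    model: PcaModel,
    labels: dict[str, str],
    level: float = 0.95,
    min_members: int = 3,
    ridge: float = 1e-9,
) -> tuple[list[ClassEllipse], list[str]]:
    """Per-class ellipses on (PC1, PC2); classes with too few labelled
    members yield no ellipse and are reported in the second return value."""
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    by_class: dict[str, list[str]] = {}
    for s in model.scores.index:
        if s in labels:
            by_class.setdefault(labels[s], []).append(s)
    ellipses: list[ClassEllipse] = []
    skipped: list[str] = []
    for cls in sorted(by_class):
        members = by_class[cls]
        if len(members) < min_members:
            skipped.append(cls)
            continue
        pts = model.scores.loc[members, ["PC1", "PC2"]].values
        center = pts.mean(axis=0)
        cov = np.cov(pts, rowvar=False, ddof=1)
        ridged = False
        if np.linalg.matrix_rank(cov) < 2 or np.linalg.cond(cov) > 1e12:
            cov = cov + ridge * np.eye(2)
            ridged = True
        ellipses.append(
            ClassEllipse(
                label=cls,
                center=center,
                covariance=cov,
                level=level,
                n_members=len(members),
                ridged=ridged,
            )
        )
    return ellipses, skipped


def classify_strains(
    model: PcaModel,
    ellipses: list[ClassEllipse],
    strains: list[str],
) -> list[ClassCall]:
    """Call each strain by ellipse membership; outclass when inside none."""
    calls: list[ClassCall] = []
    for s in strains:
        if s not in model.scores.index:
            calls.append(
                ClassCall(
                    strain_id=s,
                    call="no-call:marker-missing",
                    mahalanobis={},
                    inside=[],
                )
            )
            continue
        xy = model.scores.loc[s, ["PC1", "PC2"]].values
        md = {e.label: e.mahalanobis2(xy) for e in ellipses}
        inside = [e.label for e in ellipses if e.contains(xy)]
        if not inside:
            call, amb = "outclass", False
        elif len(inside) == 1:
            call, amb = inside[0], False
        else:
            call = min(inside, key=lambda c: (md[c], c))
            amb = True
        calls.append(
            ClassCall(strain_id=s, call=call, mahalanobis=md, inside=inside, ambiguous=amb)
        )
    return calls
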