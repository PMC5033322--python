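"""Gene-distance feature tables, Random-Forest species classification,
and marker-gene ranking by out-of-bag permutation importance.

The feature space follows the G x O construction: for every core gene g
and every reference organism o, the variable v(g, o) of a row strain s is
the genetic distance between s's copy of g and o's copy (so 109 genes x
26 organisms = 2834 variables at the published scale).  A forest of
bagged CART trees (per-split feature subsampling, majority vote) is
trained on the training strains; variable importance is Breiman's OOB
permutation measure — the mean decrease in out-of-bag accuracy when the
variable is permuted — and gene-level importance aggregates a gene's O
variables (mean by default).  Single-gene forests give each gene a test
misclassification rate, yielding the per-gene marker table
(distance mean/variance/maximum, importance, error rate).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import BaggingClassifier
from sklearn.tree import DecisionTreeClassifier

from .coregenome import GeneFamily
from .mlsa import Alignment, align_family, genetic_distance

__all__ = [
    "FeatureTable",
    "ForestModel",
    "build_feature_table",
    "gene_distance_stats",
    "train_species_forest",
    "evaluate_forest",
    "per_gene_error_rates",
    "rank_genes",
]

DEFAULT_N_TREES = 100_000
DEFAULT_SEED = 12_345


@dataclass
class FeatureTable:
    """Rows = strains, columns = v(gene, organism) distances.

    Column order is genes-major, organisms-minor and stable; metadata
    records the distance model and the (gene, organism) pair per column.
    """

    data: pd.DataFrame
    genes: list[str]
    organisms: list[str]
    labels: dict[str, str]
    model: str
    flagged_rows: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_variables(self) -> int:
        return self.data.shape[1]

    def columns_for_gene(self, gene: str) -> list[str]:
        return [f"{gene}|{o}" for o in self.organisms]

    def matrix(self, rows: list[str]) -> np.ndarray:
        return self.data.loc[rows].values


def _family_alignment(fam: GeneFamily | Alignment, needed: list[str]) -> Alignment:
    if isinstance(fam, Alignment):
        aln = fam
    else:
        seqs = fam.nucleotides()
        missing = [s for s in needed if s not in seqs]
        lens = {len(seqs[s]) for s in seqs}
        if len(lens) == 1:  # equal-length, gap-free families are pre-aligned
            ids = sorted(seqs)
            aln = Alignment(ids=ids, rows=[seqs[i] for i in ids], family_id=fam.id)
        else:
            aln = align_family(fam)
    return aln


def build_feature_table(
    core: list[GeneFamily | Alignment],
    organisms: list[str],
    rows: list[str],
    labels: dict[str, str] | None = None,
    model: str = "k80",
) -> FeatureTable:
    """Build the strains x (G x O) gene-distance feature table.

    Rows missing a gene are flagged and get NaN for that gene's block
    (no imputation).  Column count is exactly ``len(core) * len(organisms)``.
    """
    if not core or not organisms or not rows:
        raise ValueError("core families, organisms and rows must be non-empty")
    genes: list[str] = []
    cols: dict[str, np.ndarray] = {}
    flagged: dict[str, list[str]] = {}
    for fam in core:
        fam_id = fam.family_id if isinstance(fam, Alignment) else fam.id
        genes.append(fam_id)
        aln = _family_alignment(fam, list(dict.fromkeys(rows + organisms)))
        present = set(aln.ids)
        needed = [s for s in dict.fromkeys(rows + organisms) if s in present]
        dm = genetic_distance(
            Alignment(
                ids=needed,
                rows=[aln.rows[aln.ids.index(s)] for s in needed],
                family_id=fam_id,
            ),
            model=model,
        )
        for o in organisms:
            vals = np.full(len(rows), np.nan)
            for ri, s in enumerate(rows):
                if s in present and o in present:
                    vals[ri] = dm.value(s, o)
                else:
                    flagged.setdefault(s if s not in present else o, []).append(fam_id)
            cols[f"{fam_id}|{o}"] = vals
    data = pd.DataFrame(cols, index=rows)
    flagged = {k: sorted(set(v)) for k, v in flagged.items()}
    return FeatureTable(
        data=data,
        genes=genes,
        organisms=list(organisms),
        labels=dict(labels or {}),
        model=model,
        flagged_rows=flagged,
    )


def gene_distance_stats(
    core: list[GeneFamily | Alignment], model: str = "k80"
) -> pd.DataFrame:
    """Per-gene distance mean, variance (ddof=1) and maximum over all
    unordered strain pairs."""
    records = []
    for fam in core:
        fam_id = fam.family_id if isinstance(fam, Alignment) else fam.id
        aln = _family_alignment(fam, [])
        dm = genetic_distance(aln, model=model)
        vals = np.array(
            [
                dm.data[i, j]
                for i, j in itertools.combinations(range(len(dm.ids)), 2)
            ]
        )
        vals = vals[~np.isnan(vals)]
        records.append(
            {
                "gene": fam_id,
                "mean": float(vals.mean()) if vals.size else np.nan,
                "variance": float(vals.var(ddof=1)) if vals.size > 1 else 0.0,
                "maximum": float(vals.max()) if vals.size else np.nan,
            }
        )
    return pd.DataFrame(records).set_index("gene")


@dataclass
class ForestModel:
    classifier: BaggingClassifier
    feature_names: list[str]
    classes: list[str]
    variable_importance: pd.Series
    gene_importance: pd.Series
    oob_confusion: pd.DataFrame
    n_trees: int
    seed: int
    mtry: int
    aggregate: str

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classifier.predict(X)


def _oob_permutation_importance(
    clf: BaggingClassifier, X: np.ndarray, y: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Breiman's raw mean-decrease-in-OOB-accuracy per variable.

    Trees in whose out-of-bag set a variable was never used contribute a
    zero decrease; the average is over all trees.
    """
    n, V = X.shape
    importances = np.zeros(V)
    n_trees = len(clf.estimators_)
    # inner trees predict label-encoded classes; compare in encoded space
    enc = {c: i for i, c in enumerate(clf.classes_)}
    y_enc = np.array([enc[v] for v in y])
    for tree, samp in zip(clf.estimators_, clf.estimators_samples_):
        oob = np.setdiff1d(np.arange(n), np.unique(samp))
        if oob.size == 0:
            continue
        Xo, yo = X[oob], y_enc[oob]
        base = (tree.predict(Xo) == yo).mean()
        used = np.unique(tree.tree_.feature)
        used = used[used >= 0]
        for f in used:
            Xp = Xo.copy()
            Xp[:, f] = Xo[rng.permutation(oob.size), f]
            perm = (tree.predict(Xp) == yo).mean()
            importances[f] += base - perm
    return importances / n_trees


def train_species_forest(
    ft: FeatureTable,
    train_rows: list[str],
    n_trees: int = DEFAULT_N_TREES,
    seed: int = DEFAULT_SEED,
    mtry: int | None = None,
    aggregate: str = "mean",
) -> ForestModel:
    """Train the bagged-CART species classifier and compute importances.

    ``mtry`` defaults to floor(sqrt(V)).  Deterministic under ``seed``.
    """
    if aggregate not in ("mean", "sum", "max"):
        raise ValueError("aggregate must be mean, sum or max")
    y = np.array([ft.labels[s] for s in train_rows])
    if len(set(y)) < 2:
        raise ValueError("training rows must span >= 2 species classes")
    X = ft.matrix(train_rows)
    if np.isnan(X).any():
        bad = [s for s in train_rows if np.isnan(ft.data.loc[s].values).any()]
        raise ValueError(f"training rows with missing features: {bad}")
    V = X.shape[1]
    mtry = mtry or max(1, int(np.sqrt(V)))
    clf = BaggingClassifier(
        estimator=DecisionTreeClassifier(max_features=mtry, random_state=0),
        n_estimators=n_trees,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    clf.fit(X, y)
    rng = np.random.default_rng(seed)
    imp = pd.Series(
        _oob_permutation_importance(clf, X, y, rng), index=ft.data.columns
    )
    per_gene = {}
    for g in ft.genes:
        block = imp[ft.columns_for_gene(g)]
        per_gene[g] = {"mean": block.mean(), "sum": block.sum(), "max": block.max()}[
            aggregate
        ]
    gene_imp = pd.Series(per_gene)

    # OOB majority-vote confusion over the training rows
    n = len(train_rows)
    classes = list(clf.classes_)
    votes = np.zeros((len(classes), n))
    for tree, samp in zip(clf.estimators_, clf.estimators_samples_):
        oob = np.setdiff1d(np.arange(n), np.unique(samp))
        if oob.size == 0:
            continue
        pred = tree.predict(X[oob])  # label-encoded class indices
        for i, p in zip(oob, pred):
            votes[int(p), i] += 1
    oob_pred = np.array([classes[i] for i in votes.argmax(axis=0)])
    conf = pd.crosstab(
        pd.Series(y, name="truth"), pd.Series(oob_pred, name="oob_prediction")
    ).reindex(index=classes, columns=classes, fill_value=0)
    return ForestModel(
        classifier=clf,
        feature_names=list(ft.data.columns),
        classes=classes,
        variable_importance=imp,
        gene_importance=gene_imp,
        oob_confusion=conf,
        n_trees=n_trees,
        seed=seed,
        mtry=mtry,
        aggregate=aggregate,
    )


def evaluate_forest(
    model: ForestModel, ft: FeatureTable, test_rows: list[str]
) -> tuple[pd.DataFrame, float]:
    """Confusion table and misclassification rate on the test strains."""
    if not test_rows:
        raise ValueError("empty test set")
    X = ft.data.loc[test_rows, model.feature_names].values
    if np.isnan(X).any():
        bad = [s for s in test_rows if np.isnan(ft.data.loc[s].values).any()]
        raise ValueError(f"test rows with missing features: {bad}")
    pred = model.predict(X)
    truth = np.array([ft.labels[s] for s in test_rows])
    classes = sorted(set(model.classes) | set(truth))
    conf = pd.crosstab(
        pd.Series(truth, name="truth"), pd.Series(pred, name="prediction")
    ).reindex(index=classes, columns=classes, fill_value=0)
    rate = float((pred != truth).mean())
    return conf, rate


def per_gene_error_rates(
    ft: FeatureTable,
    train_rows: list[str],
    test_rows: list[str],
    n_trees: int = DEFAULT_N_TREES,
    seed: int = DEFAULT_SEED,
) -> pd.Series:
    """Train one forest per gene on only that gene's O columns and report
    its test-set misclassification rate."""
    y_train = np.array([ft.labels[s] for s in train_rows])
    y_test = np.array([ft.labels[s] for s in test_rows])
    rates = {}
    for g in ft.genes:
        cols = ft.columns_for_gene(g)
        Xtr = ft.data.loc[train_rows, cols].values
        Xte = ft.data.loc[test_rows, cols].values
        if np.isnan(Xtr).any() or np.isnan(Xte).any():
            rates[g] = np.nan  # abstain: missing orthologs, no imputation
            continue
        mtry = max(1, int(np.sqrt(len(cols))))
        clf = BaggingClassifier(
            estimator=DecisionTreeClassifier(max_features=mtry, random_state=0),
            n_estimators=n_trees,
            bootstrap=True,
            random_state=seed,
            n_jobs=1,
        )
        clf.fit(Xtr, y_train)
        rates[g] = float((clf.predict(Xte) != y_test).mean())
    return pd.Series(rates, name="error_rate")


def rank_genes(
    stats: pd.DataFrame,
    importance: pd.Series,
    error_rates: pd.Series | None = None,
) -> pd.DataFrame:
    """Ranked marker table: descending importance; ties broken by lower
    error rate, then higher distance mean, then gene id."""
    df = stats.copy()
    df["importance"] = importance
    df["error_rate"] = error_rates if error_rates is not None else np.nan
    df = (
        df.reset_index()
        .sort_values(
            by=["importance", "error_rate", "mean", "gene"],
            ascending=[False, True, False, True],
            na_position="last",
        )
        .set_index("gene")
    )
    df.insert(0, "rank", range(1, len(df) + 1))
    return df
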