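"""Reconcile secretory-granule proteomes with annotation-based confidence scores.

Several published proteomes of the insulin secretory granule (ISG) disagree
substantially, partly because each isolation protocol carries over impurities
from other compartments.  This module scores every protein in the pooled
roster by how strongly its cellular-location annotations (and those of its
interaction partners) resemble the annotations of a curated set of bona fide
granule proteins, weighted by how many of the proteomes detected it.

The scoring scheme:

* For every location keyword ``k`` (e.g. ``"cytoplasmic vesicle"``,
  ``"mitochondrion"``) a discrimination score is computed from a labelled
  positive/negative split of the roster::

      LocScore(k) = fracPos(k) - fracNeg(k)

  where ``fracPos`` is the fraction of labelled positives carrying ``k`` and
  ``fracNeg`` the fraction of negatives.  Keywords typical of granule proteins
  score towards +1, keywords typical of impurities (nucleus, mitochondrion)
  score negative.  The same construction applied to the keywords of annotated
  interaction partners yields ``IntLocScore``.

* A protein's raw confidence is::

      raw(p) = N_proteome(p) * (W_loc * sum LocScore + W_intloc * sum IntLocScore)

  with ``N_proteome`` the number of proteomes that include the protein.  Raw
  scores are min-max normalised over the scored roster to [0, 1].

* The two weights are selected by a grid sweep maximising the ROC AUC of the
  confidence values against the labels (defaults ``W_loc=12, W_intloc=1``).

No cross-validation is applied: the labelled positives are part of the scored
set, so their high scores are partly training bias.  This is a documented
caveat of the procedure, not corrected here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_WEIGHTS = (12.0, 1.0)
#: Review threshold on the normalised confidence (strict inequality) and the
#: minimum proteome-membership count that flags a protein regardless of score.
DEFAULT_THRESHOLD = 0.333
DEFAULT_MIN_PROTEOMES = 2

Flavour = Literal["location", "interactor"]


@dataclass(frozen=True)
class AnnotationCatalog:
    """Per-protein annotation evidence.

    Parameters
    ----------
    loc
        protein id -> set of location keywords of the protein itself.
    intloc
        protein id -> multiset (tuple, multiplicity preserved) of location
        keywords contributed by annotated interaction partners.  Each partner
        contributes its keyword *set* once; the tuples here are the
        concatenation over partners.
    proteomes
        protein id -> set of proteome identifiers the protein appears in.
    """

    loc: Mapping[str, frozenset]
    intloc: Mapping[str, tuple]
    proteomes: Mapping[str, frozenset]

    def __post_init__(self):
        roster = set(self.proteomes)
        if set(self.loc) - roster or set(self.intloc) - roster:
            raise ValueError("loc/intloc contain proteins missing from the proteome roster")
        for pid, members in self.proteomes.items():
            if len(members) < 1:
                raise ValueError(f"protein {pid!r} has no proteome membership")

    @property
    def roster(self) -> list:
        return sorted(self.proteomes)

    def n_proteome(self, protein_id: str) -> int:
        return len(self.proteomes[protein_id])


@dataclass(frozen=True)
class LabelledSet:
    """Curated true positives and trial negatives partitioning the roster."""

    positives: frozenset
    negatives: frozenset

    def __post_init__(self):
        if self.positives & self.negatives:
            raise ValueError("positives and negatives overlap")


@dataclass(frozen=True)
class ConfidenceWeights:
    w_loc: float = DEFAULT_WEIGHTS[0]
    w_intloc: float = DEFAULT_WEIGHTS[1]

    def __post_init__(self):
        if self.w_loc < 0 or self.w_intloc < 0:
            raise ValueError("weights must be nonnegative")


def build_score_table(
    catalog: AnnotationCatalog, labels: LabelledSet, flavour: Flavour
) -> pd.DataFrame:
    """Score every keyword observed in the catalog by label discrimination.

    Returns a DataFrame indexed by keyword with columns ``frac_pos``,
    ``frac_neg`` and ``score = frac_pos - frac_neg``.  A keyword's fraction is
    the share of labelled proteins on that side carrying the keyword at least
    once.
    """
    if not labels.positives or not labels.negatives:
        raise ValueError("both labelled sides must be nonempty")
    if flavour == "location":
        carrier = {p: frozenset(catalog.loc.get(p, frozenset())) for p in catalog.roster}
    elif flavour == "interactor":
        carrier = {p: frozenset(catalog.intloc.get(p, ())) for p in catalog.roster}
    else:
        raise ValueError(f"unknown flavour {flavour!r}")

    keywords = sorted(set().union(*carrier.values()) if carrier else set())
    n_pos = len(labels.positives)
    n_neg = len(labels.negatives)
    rows = []
    for kw in keywords:
        fp = sum(1 for p in labels.positives if kw in carrier.get(p, ())) / n_pos
        fn = sum(1 for p in labels.negatives if kw in carrier.get(p, ())) / n_neg
        rows.append((kw, fp, fn, fp - fn))
    table = pd.DataFrame(rows, columns=["keyword", "frac_pos", "frac_neg", "score"])
    return table.set_index("keyword")


def _keyword_sum(keywords: Iterable, table: pd.DataFrame) -> float:
    score = table["score"]
    return float(sum(score.get(kw, 0.0) for kw in keywords))


def raw_scores(
    catalog: AnnotationCatalog,
    loc_table: pd.DataFrame,
    intloc_table: pd.DataFrame,
    weights: ConfidenceWeights = ConfidenceWeights(),
) -> pd.DataFrame:
    """Raw (unnormalised) confidence for every protein in the roster.

    Columns: ``raw``, ``n_proteome``, ``loc_sum``, ``intloc_sum``.
    """
    rows = []
    for pid in catalog.roster:
        loc_sum = _keyword_sum(catalog.loc.get(pid, frozenset()), loc_table)
        intloc_sum = _keyword_sum(catalog.intloc.get(pid, ()), intloc_table)
        n = catalog.n_proteome(pid)
        raw = n * (weights.w_loc * loc_sum + weights.w_intloc * intloc_sum)
        rows.append((pid, raw, n, loc_sum, intloc_sum))
    df = pd.DataFrame(rows, columns=["id", "raw", "n_proteome", "loc_sum", "intloc_sum"])
    return df.set_index("id")


def score_all(
    catalog: AnnotationCatalog,
    loc_table: pd.DataFrame,
    intloc_table: pd.DataFrame,
    weights: ConfidenceWeights = ConfidenceWeights(),
) -> pd.DataFrame:
    """Confidence values for the whole roster, min-max normalised to [0, 1].

    If all raw scores are identical the normalised value is 0 for every
    protein (degenerate span).
    """
    df = raw_scores(catalog, loc_table, intloc_table, weights)
    lo, hi = df["raw"].min(), df["raw"].max()
    span = hi - lo
    df["value"] = 0.0 if span == 0 else (df["raw"] - lo) / span
    return df


def confidence(
    protein_id: str,
    catalog: AnnotationCatalog,
    loc_table: pd.DataFrame,
    intloc_table: pd.DataFrame,
    weights: ConfidenceWeights = ConfidenceWeights(),
) -> pd.Series:
    """Confidence record for one protein (normalised over the full roster)."""
    if protein_id not in catalog.proteomes:
        raise KeyError(f"protein {protein_id!r} not in catalog")
    return score_all(catalog, loc_table, intloc_table, weights).loc[protein_id]


def roc_auc(values: Sequence[float], labels: Sequence[bool]) -> float:
    """Area under the ROC curve with midrank tie handling.

    Equivalent to the Mann-Whitney U statistic divided by ``n_pos * n_neg``.
    """
    labels = np.asarray(labels, dtype=bool)
    values = np.asarray(values, dtype=float)
    if labels.all() or (~labels).all():
        raise ValueError("roc_auc requires both classes")
    from sklearn.metrics import roc_auc_score

    return float(roc_auc_score(labels, values))


def sweep_weights(
    catalog: AnnotationCatalog,
    labels: LabelledSet,
    grid: Sequence[tuple],
    loc_table: pd.DataFrame | None = None,
    intloc_table: pd.DataFrame | None = None,
) -> ConfidenceWeights:
    """Select the weight pair maximising ROC AUC of confidence vs. labels.

    Ties (to within 1e-12) are broken by smallest ``w_loc`` then smallest
    ``w_intloc``.  Score tables are built once from the labels unless passed
    in explicitly.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty weight grid")
    if loc_table is None:
        loc_table = build_score_table(catalog, labels, "location")
    if intloc_table is None:
        intloc_table = build_score_table(catalog, labels, "interactor")
    label_vec = [p in labels.positives for p in catalog.roster]

    results = []
    for w_loc, w_intloc in grid:
        df = raw_scores(catalog, loc_table, intloc_table, ConfidenceWeights(w_loc, w_intloc))
        auc = roc_auc(df["raw"].to_numpy(), label_vec)
        results.append((auc, w_loc, w_intloc))
    best_auc = max(r[0] for r in results)
    contenders = [(wl, wi) for auc, wl, wi in results if auc >= best_auc - 1e-12]
    w_loc, w_intloc = min(contenders)
    return ConfidenceWeights(w_loc, w_intloc)


def rank_and_flag(
    scores: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    min_proteomes: int = DEFAULT_MIN_PROTEOMES,
) -> pd.DataFrame:
    """Rank scored proteins and flag the ones deserving manual review.

    A protein is flagged when its confidence strictly exceeds ``threshold``
    *or* it appears in at least ``min_proteomes`` proteomes.  Output is sorted
    by descending value, ties broken lexicographically by id.
    """
    df = scores.copy()
    df["flagged"] = (df["value"] > threshold) | (df["n_proteome"] >= min_proteomes)
    df = df.reset_index()
    df = df.sort_values(["value", "id"], ascending=[False, True]).set_index("id")
    return df


# ---------------------------------------------------------------------------
# Delimited-text interfaces
# ---------------------------------------------------------------------------

def read_catalog(path) -> AnnotationCatalog:
    """Read an annotation catalog from TSV.

    Expected columns: ``id``, ``proteomes``, ``loc``, ``intloc``; the last
    three are ``;``-separated lists (``intloc`` with multiplicity).
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")

    def split(s):
        return tuple(x for x in s.split(";") if x)

    return AnnotationCatalog(
        loc={r["id"]: frozenset(split(r["loc"])) for _, r in df.iterrows()},
        intloc={r["id"]: split(r["intloc"]) for _, r in df.iterrows()},
        proteomes={r["id"]: frozenset(split(r["proteomes"])) for _, r in df.iterrows()},
    )


def write_catalog(catalog: AnnotationCatalog, path) -> None:
    rows = [
        {
            "id": pid,
            "proteomes": ";".join(sorted(catalog.proteomes[pid])),
            "loc": ";".join(sorted(catalog.loc.get(pid, frozenset()))),
            "intloc": ";".join(catalog.intloc.get(pid, ())),
        }
        for pid in catalog.roster
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_ranked(df: pd.DataFrame, path) -> None:
    """Write the ranked confidence table as TSV."""
    out = df.reset_index()[["id", "value", "n_proteome", "loc_sum", "intloc_sum", "flagged"]]
    out.to_csv(path, sep="\t", index=False)


def read_labels(path) -> LabelledSet:
    """Read a two-column TSV ``id, label`` with label in {positive, negative}."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    pos = frozenset(df.loc[df["label"] == "positive", "id"])
    neg = frozenset(df.loc[df["label"] == "negative", "id"])
    return LabelledSet(pos, neg)
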