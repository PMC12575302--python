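"""Knowledge fusion: TF-IDF terminology matching with tiered mapping.

Clinical records written by different doctors use variant surface forms of
the same concept, so extracted entities are normalised against reference
terminologies.  Each reference term is one "document"; features are
character n-grams (default range (1, 2)), which capture the shared-substring
structure of Chinese term variants.  Weights follow the classic scheme

    TF(t, d)  = count of feature t in d / total features in d
    IDF(t)    = ln( N / |{d : t in d}| )          (no smoothing by default)
    w(t, d)   = TF(t, d) * IDF(t)

and a query is scored against every reference term by cosine similarity of
the weighted vectors.  Mapping decisions are three-tiered:

* similarity > 0.75          -> ``auto`` (merged automatically)
* 0.6 <= similarity <= 0.75  -> ``review`` (queued for manual review)
* similarity < 0.6           -> ``reject`` (kept as a distinct entity)

Disease/symptom entities are routed to the website-derived reference corpus
and treatment/operation entities to the terminology-standard corpus; types
with no configured reference pass through unmapped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

TIER_AUTO = "auto"
TIER_REVIEW = "review"
TIER_REJECT = "reject"

#: default entity-type -> reference-corpus routing
DEFAULT_ROUTING: dict[str, str] = {
    "diseases": "website",
    "symptom": "website",
    "treatment_options": "terminology",
    "operation_recording": "terminology",
}


def char_ngrams(term: str, ngram_range: tuple[int, int] = (1, 2)) -> list[str]:
    """All character n-grams of the term for n in the inclusive range."""
    lo, hi = ngram_range
    out = []
    for n in range(lo, hi + 1):
        out.extend(term[i : i + n] for i in range(len(term) - n + 1))
    return out


@dataclass
class TfidfModel:
    """Reference terminology fitted as a TF-IDF vector space."""

    vocabulary: dict[str, int]
    idf: np.ndarray
    reference_terms: list[str]
    reference_matrix: np.ndarray  # (n_terms, n_features) TF-IDF rows
    ngram_range: tuple[int, int] = (1, 2)
    smooth: bool = False


@dataclass(frozen=True)
class MappingDecision:
    query: str
    best_match: str | None
    similarity: float
    tier: str


def _tf_vector(term: str, model: TfidfModel) -> np.ndarray:
    """Eq-style TF over the term's own features; unseen features dropped."""
    grams = char_ngrams(term, model.ngram_range)
    vec = np.zeros(len(model.vocabulary))
    if not grams:
        return vec
    inv_total = 1.0 / len(grams)
    for g in grams:
        j = model.vocabulary.get(g)
        if j is not None:
            vec[j] += inv_total
    return vec


def fit_tfidf(
    reference_terms: Iterable[str], ngram_range: tuple[int, int] = (1, 2),
    smooth: bool = False,
) -> TfidfModel:
    """Fit the vector space on a reference corpus (one term = one document).

    ``smooth`` adds 1 to document frequencies, for corpora where a feature
    of an incoming query might otherwise divide by zero; the default is the
    literal unsmoothed formula.
    """
    terms = [t for t in reference_terms if t]
    if not terms:
        raise ValueError("reference corpus has no non-empty terms")
    vocabulary: dict[str, int] = {}
    doc_features = []
    for term in terms:
        grams = char_ngrams(term, ngram_range)
        doc_features.append(grams)
        for g in grams:
            vocabulary.setdefault(g, len(vocabulary))

    n_docs = len(terms)
    df = np.zeros(len(vocabulary))
    for grams in doc_features:
        for j in {vocabulary[g] for g in grams}:
            df[j] += 1
    if smooth:
        idf = np.log((n_docs + 1) / (df + 1))
    else:
        idf = np.log(n_docs / df)

    model = TfidfModel(
        vocabulary=vocabulary,
        idf=idf,
        reference_terms=terms,
        reference_matrix=np.empty((0, 0)),
        ngram_range=ngram_range,
        smooth=smooth,
    )
    model.reference_matrix = np.stack([vectorize(t, model) for t in terms])
    return model


def vectorize(term: str, model: TfidfModel) -> np.ndarray:
    """TF-IDF vector of a term in the model's feature space."""
    if not term:
        logger.warning("vectorizing empty term; returning zero vector")
        return np.zeros(len(model.vocabulary))
    return _tf_vector(term, model) * model.idf


def cosine(v1: np.ndarray, v2: np.ndarray) -> float:
    """Cosine similarity, defined as 0 when either vector has zero norm.

    For nonnegative inputs the value lies in [0, 1]; floating-point noise
    within 1e-12 of the bounds is snapped to the exact bound, so a term
    matched against itself scores exactly 1.
    """
    v1 = np.asarray(v1, float)
    v2 = np.asarray(v2, float)
    if v1.shape != v2.shape:
        raise ValueError(f"dimension mismatch: {v1.shape} vs {v2.shape}")
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0.0 or n2 == 0.0:
        return 0.0
    s = float(v1 @ v2 / (n1 * n2))
    if abs(s - 1.0) < 1e-12:
        return 1.0
    if abs(s) < 1e-15:
        return 0.0
    return s


def map_entity(
    query: str,
    model: TfidfModel,
    auto_threshold: float = 0.75,
    review_threshold: float = 0.6,
) -> MappingDecision:
    """Best-match mapping with the three-tier thresholds.

    Boundary semantics are exact: strictly greater than ``auto_threshold``
    for automatic mapping, the closed interval [review, auto] for manual
    review, strictly below ``review_threshold`` for rejection.  Ties between
    reference terms break toward the lexicographically smallest term.
    """
    if not 0.0 <= review_threshold <= auto_threshold <= 1.0:
        raise ValueError(
            f"require 0 <= review <= auto <= 1, got ({review_threshold}, {auto_threshold})"
        )
    qv = vectorize(query, model)
    qn = np.linalg.norm(qv)
    if qn == 0.0:
        sims = np.zeros(len(model.reference_terms))
    else:
        ref = model.reference_matrix
        norms = np.linalg.norm(ref, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            sims = np.where(norms > 0, ref @ qv / (norms * qn), 0.0)
        sims = np.where(np.abs(sims - 1.0) < 1e-12, 1.0, sims)

    best_sim = float(sims.max()) if len(sims) else 0.0
    candidates = [
        model.reference_terms[i] for i in np.flatnonzero(sims == best_sim)
    ]
    best = min(candidates) if candidates else None

    if best_sim > auto_threshold:
        tier = TIER_AUTO
    elif best_sim >= review_threshold:
        tier = TIER_REVIEW
    else:
        tier = TIER_REJECT
    return MappingDecision(
        query, None if tier == TIER_REJECT else best, best_sim, tier
    )


@dataclass
class FusionResult:
    decisions: list[MappingDecision] = field(default_factory=list)
    review_queue: list[MappingDecision] = field(default_factory=list)

    def canonical(self, query: str) -> str:
        """Canonical surface for a query: its auto-tier match, else itself
        (review-tier entities are never auto-merged)."""
        for d in self.decisions:
            if d.query == query and d.tier == TIER_AUTO and d.best_match:
                return d.best_match
        return query


def route_by_type(
    entities: Sequence[tuple[str, str]],
    models: Mapping[str, TfidfModel],
    routing: Mapping[str, str] | None = None,
    auto_threshold: float = 0.75,
    review_threshold: float = 0.6,
) -> list[tuple[str, str, MappingDecision]]:
    """Map (entity_type, surface) pairs via their type's reference corpus.

    ``routing`` maps entity types to corpus names, ``models`` corpus names to
    fitted models.  A routed-but-missing corpus is a configuration error;
    unrouted types pass through unmapped with tier ``reject``.
    """
    if routing is None:
        routing = DEFAULT_ROUTING
    out = []
    for etype, surface in entities:
        corpus = routing.get(etype)
        if corpus is None:
            decision = MappingDecision(surface, None, 0.0, TIER_REJECT)
        elif corpus not in models:
            raise KeyError(
                f"entity type {etype!r} routed to missing reference corpus {corpus!r}"
            )
        else:
            decision = map_entity(
                surface, models[corpus], auto_threshold, review_threshold
            )
        out.append((etype, surface, decision))
    return out


def fuse(
    entities: Sequence[tuple[str, str]],
    models: Mapping[str, TfidfModel],
    routing: Mapping[str, str] | None = None,
    auto_threshold: float = 0.75,
    review_threshold: float = 0.6,
) -> FusionResult:
    """Full fusion pass; review-tier decisions go to the manual queue."""
    result = FusionResult()
    for _etype, _surface, d in route_by_type(
        entities, models, routing, auto_threshold, review_threshold
    ):
        result.decisions.append(d)
        if d.tier == TIER_REVIEW:
            result.review_queue.append(d)
    return result


def write_mapping_report(decisions: Sequence[MappingDecision], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("query\tbest_match\tsimilarity\ttier\n")
        for d in decisions:
            fh.write(f"{d.query}\t{d.best_match or ''}\t{d.similarity:.6f}\t{d.tier}\n")


def read_reference_terms(path) -> list[str]:
    """UTF-8 reference corpus, one canonical term per line."""
    with open(path, "r", encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]
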