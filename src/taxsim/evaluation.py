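"""The HLOS prediction experiment: nearest-prototype classification and sweeps.

A target patient is classified into the HLOS class (short: ≤ 18 days; long:
≥ 19 days) of whichever of the two prototypes of their age stratum is nearer
under a chosen ⟨IC, CS, SS⟩ combination. The positive class is *short*
throughout: precision, recall and the F-score (harmonic mean) measure the
classifier's ability to recognise patients who will be discharged within 18
days, sweeping the prototype size k and the combination grid.

Also here: the Pearson correlation between the prototype-distance curves of
the CS-aggregating SS measures, and a classical (Torgerson) multidimensional
scaling embedding for visual inspection of concept distance matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .concept_distance import CSMethod
from .errors import ConfigurationError, DomainError
from .information_content import ICMethod
from .prototype import PatientRecord, Prototype
from .set_distance import SSMethod, set_distance
from .taxonomy import Taxonomy

__all__ = [
    "CombinationTriple",
    "STANDARD_TRIPLES",
    "EvaluationResult",
    "SHORT_HLOS_MAX",
    "classify_patient",
    "evaluate",
    "sweep",
    "ss_correlation",
    "mds_embed",
]

logger = logging.getLogger("taxsim")

#: HLOS (days) at or below which a stay counts as "short" (the positive class).
SHORT_HLOS_MAX = 18

_IC_BY_NUM = {1: ICMethod.PATH, 2: ICMethod.ONTOLOGY}
_CS_BY_NUM = {1: "binary", 2: "wu", 3: "li", 4: "simplified"}
_SS_BY_NUM = {
    1: SSMethod.DICE, 2: SSMethod.JACCARD, 3: SSMethod.COSINE, 4: SSMethod.OVERLAP,
    5: SSMethod.CLOSEST_PAIR, 6: SSMethod.NONSHARED_AVG,
    7: SSMethod.ALLPAIRS_AVG, 8: SSMethod.BIPARTITE,
}


@dataclass(frozen=True)
class CombinationTriple:
    """One full ⟨IC, CS, SS⟩ configuration of the three algorithm levels."""

    ic: ICMethod
    cs: CSMethod
    ss: SSMethod

    @property
    def name(self) -> str:
        ic_num = {v: k for k, v in _IC_BY_NUM.items()}[self.ic]
        cs_num = {v: k for k, v in _CS_BY_NUM.items()}[self.cs.method_id]
        ss_num = {v: k for k, v in _SS_BY_NUM.items()}[self.ss]
        return f"<{ic_num},{cs_num},{ss_num}>"

    @classmethod
    def from_numbers(cls, ic_num: int, cs_num: int, ss_num: int) -> "CombinationTriple":
        try:
            return cls(_IC_BY_NUM[ic_num], CSMethod(_CS_BY_NUM[cs_num]), _SS_BY_NUM[ss_num])
        except KeyError as exc:
            raise ConfigurationError(f"no such method number in triple "
                                     f"<{ic_num},{cs_num},{ss_num}>") from exc

    @classmethod
    def parse(cls, name: str) -> "CombinationTriple":
        """Parse a canonical name like ``"<1,2,8>"``."""
        body = name.strip().lstrip("<").rstrip(">")
        try:
            ic_num, cs_num, ss_num = (int(x) for x in body.split(","))
        except ValueError:
            raise ConfigurationError(f"cannot parse triple name {name!r}") from None
        return cls.from_numbers(ic_num, cs_num, ss_num)


#: The ten studied combinations: ⟨1,2,5..8⟩, ⟨2,2,5..8⟩, ⟨1,3,8⟩, ⟨1,4,8⟩.
STANDARD_TRIPLES: tuple[CombinationTriple, ...] = tuple(
    CombinationTriple.from_numbers(i, c, s)
    for (i, c, ss_list) in ((1, 2, (5, 6, 7, 8)), (2, 2, (5, 6, 7, 8)),
                            (1, 3, (8,)), (1, 4, (8,)))
    for s in ss_list
)


@dataclass(frozen=True)
class EvaluationResult:
    """Precision/recall/F-score of one triple at one prototype size."""

    triple_name: str
    k: int
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n_test(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def precision(self) -> float:
        denom = self.tp + self.fp
        if denom == 0:
            logger.warning("no predicted positives for %s at k=%d; precision reported as 0",
                           self.triple_name, self.k)
            return 0.0
        return self.tp / denom

    @property
    def recall(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else 0.0

    @property
    def fscore(self) -> float:
        p, r = self.precision, self.recall
        return 2.0 * p * r / (p + r) if (p + r) else 0.0


def classify_patient(
    taxonomy: Taxonomy,
    triple: CombinationTriple,
    patient: PatientRecord,
    proto_short: Prototype,
    proto_long: Prototype,
    k: int,
) -> str:
    """Label the patient ``"short"`` or ``"long"`` by the nearer prototype's top-k set.

    Exact distance ties are broken deterministically toward ``"short"`` with
    a logged warning (ties are measure-zero for real-valued distances but
    must be reproducible).
    """
    d_short = set_distance(taxonomy, triple.ic, triple.cs, triple.ss,
                           patient.codes, proto_short.top_k(k))
    d_long = set_distance(taxonomy, triple.ic, triple.cs, triple.ss,
                          patient.codes, proto_long.top_k(k))
    if d_short == d_long:
        logger.warning("distance tie for patient %s at k=%d (%s); assigning 'short'",
                       patient.patient_id, k, triple.name)
        return "short"
    return "short" if d_short < d_long else "long"


def _proto_pair_for(patient: PatientRecord,
                    protos: Mapping[str, Prototype]) -> tuple[Prototype, Prototype]:
    """The (short, long) prototype pair of the patient's age stratum."""
    candidates = [
        p for p in protos.values()
        if p.source_spec is not None
        and p.source_spec.age_min <= patient.age <= p.source_spec.age_max
    ]
    short = [p for p in candidates if p.source_spec.hlos_max <= SHORT_HLOS_MAX]
    long_ = [p for p in candidates if p.source_spec.hlos_min > SHORT_HLOS_MAX]
    if len(short) != 1 or len(long_) != 1:
        raise ConfigurationError(
            f"patient {patient.patient_id!r} (age {patient.age}) does not map to exactly "
            "one short and one long prototype"
        )
    return short[0], long_[0]


def evaluate(
    taxonomy: Taxonomy,
    triple: CombinationTriple,
    test: Sequence[PatientRecord],
    protos: Mapping[str, Prototype],
    k: int,
) -> EvaluationResult:
    """Score the nearest-prototype classifier on a test set.

    ``protos`` maps stratum labels to the four prototypes; each test patient
    is matched against the short/long pair of their own age stratum. The
    positive class is short HLOS (≤ 18 days); the patient's real HLOS is the
    gold standard.
    """
    if not test:
        raise DomainError("empty test set")
    tp = fp = fn = tn = 0
    for patient in test:
        proto_short, proto_long = _proto_pair_for(patient, protos)
        predicted = classify_patient(taxonomy, triple, patient, proto_short, proto_long, k)
        actual = "short" if patient.hlos <= SHORT_HLOS_MAX else "long"
        if predicted == "short":
            if actual == "short":
                tp += 1
            else:
                fp += 1
        else:
            if actual == "short":
                fn += 1
            else:
                tn += 1
    return EvaluationResult(triple.name, k, tp, fp, fn, tn)


def sweep(
    taxonomy: Taxonomy,
    triples: Iterable[CombinationTriple],
    test: Sequence[PatientRecord],
    protos_by_triple: Mapping[tuple[ICMethod, CSMethod], Mapping[str, Prototype]],
    ks: Sequence[int],
) -> list[EvaluationResult]:
    """Full grid of results over triples × prototype sizes.

    ``protos_by_triple`` maps each (IC, CS) pair to its stratum prototypes —
    prototypes depend only on those two slots, so they are built once per
    pair and shared across the SS methods.
    """
    if list(ks) != sorted(set(ks)):
        raise DomainError("ks must be strictly ascending")
    results = []
    for triple in triples:
        protos = protos_by_triple[(triple.ic, triple.cs)]
        max_k = min(len(p) for p in protos.values())
        for k in ks:
            results.append(evaluate(taxonomy, triple, test, protos, min(k, max_k)))
    return results


def ss_correlation(
    taxonomy: Taxonomy,
    ic_method: ICMethod | str,
    cs: CSMethod | str,
    proto_a: Prototype,
    proto_b: Prototype,
    ks: Sequence[int],
    ss_methods: Sequence[SSMethod | str] = (
        SSMethod.CLOSEST_PAIR, SSMethod.NONSHARED_AVG,
        SSMethod.ALLPAIRS_AVG, SSMethod.BIPARTITE,
    ),
) -> tuple[list[SSMethod], np.ndarray]:
    """Pearson correlation between SS methods' prototype-distance-vs-k curves.

    Returns the method list and the correlation matrix; entries involving a
    constant curve are reported as NaN (correlation undefined).
    """
    if len(ks) < 3:
        raise DomainError("need at least 3 prototype sizes for a correlation")
    methods = [SSMethod.parse(m) for m in ss_methods]
    curves = np.array([
        [set_distance(taxonomy, ic_method, cs, m, proto_a.top_k(k), proto_b.top_k(k))
         for k in ks]
        for m in methods
    ])
    n = len(methods)
    corr = np.full((n, n), np.nan)
    sd = curves.std(axis=1)
    for i in range(n):
        for j in range(n):
            if sd[i] > 0 and sd[j] > 0:
                corr[i, j] = float(np.corrcoef(curves[i], curves[j])[0, 1])
    return methods, corr


def mds_embed(dist, dims: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS coordinates from a distance matrix.

    Double-centres −½·D², takes the top ``dims`` eigenvectors scaled by the
    square root of their (non-negative part of the) eigenvalues. The result
    is deterministic up to sign and rotation; compare embedded distances,
    not raw coordinates.
    """
    D = np.asarray(dist, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise DomainError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise DomainError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-10):
        raise DomainError("distance matrix must have a zero diagonal")
    n = D.shape[0]
    if n < dims + 1:
        raise DomainError(f"need at least {dims + 1} points for a {dims}-D embedding")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1][:dims]
    lams = np.clip(eigvals[order], 0.0, None)
    return eigvecs[:, order] * np.sqrt(lams)
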