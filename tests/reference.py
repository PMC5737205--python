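"""Independent brute-force oracles used to cross-check the package.

Everything here is written directly from the textbook definitions with
naive dense loops, deliberately sharing no code with the package's
optimized implementations.
"""

from __future__ import annotations

import math

import numpy as np


# -- retrieval scoring -------------------------------------------------------

def brute_force_score(clauses, doc_fields, all_docs_fields) -> float:
    """Score per the stated formula, recomputing every statistic by counting.

    clauses: list of (field, [(term, boost), ...])
    doc_fields: {field: [token, ...]} for the scored document
    all_docs_fields: {doc_id: {field: [token, ...]}} for the collection
    """
    n = len(all_docs_fields)
    total_pairs = sum(len({t for t, _ in terms}) for _, terms in clauses)
    matched = 0
    acc = 0.0
    for field, terms in clauses:
        tokens = doc_fields.get(field, [])
        if not tokens:
            continue
        seen = set()
        for term, boost in terms:
            if term in seen:
                continue
            seen.add(term)
            tf = tokens.count(term)
            if tf == 0:
                continue
            df = sum(
                1 for fields in all_docs_fields.values()
                if term in fields.get(field, [])
            )
            idf = 1.0 + math.log(n / (df + 1))
            matched += 1
            acc += (
                math.sqrt(tf) * idf * idf * boost / math.sqrt(len(tokens))
            )
    if matched == 0 or total_pairs == 0:
        return 0.0
    return (matched / total_pairs) * acc


# -- evaluation metrics ------------------------------------------------------

def _binary(grades, doc):
    return 1 if grades.get(doc, -1) >= 1 else 0


def ref_precision_at_k(ranking, grades, k):
    rels = [_binary(grades, d) for d in ranking[:k]]
    rels += [0] * (k - len(rels))
    return sum(rels) / k


def ref_recall(ranking, grades, cutoff=None):
    total = sum(1 for g in grades.values() if g >= 1)
    docs = ranking if cutoff is None else ranking[:cutoff]
    return sum(_binary(grades, d) for d in docs) / total


def ref_average_precision(ranking, grades):
    total = sum(1 for g in grades.values() if g >= 1)
    acc = 0.0
    for i, doc in enumerate(ranking):
        if _binary(grades, doc):
            acc += sum(_binary(grades, d) for d in ranking[: i + 1]) / (i + 1)
    return acc / total


def ref_ndcg(ranking, grades, k=None):
    docs = ranking if k is None else ranking[:k]
    gains = [2 ** grades[d] - 1 if grades.get(d, -1) > 0 else 0 for d in docs]
    dcg = sum(g / math.log2(i + 2) for i, g in enumerate(gains))
    ideal = sorted(
        (2 ** g - 1 for g in grades.values() if g > 0), reverse=True
    )
    if k is not None:
        ideal = ideal[:k]
    idcg = sum(g / math.log2(i + 2) for i, g in enumerate(ideal))
    return dcg / idcg if idcg else None


# -- Rocchio -----------------------------------------------------------------

def dense_rocchio(qvec, dr_vecs, dnr_vecs, alpha, beta, gamma):
    """Dense numpy evaluation of the Rocchio combination with clamping."""
    vocab = sorted(
        set(qvec)
        | {t for v in dr_vecs for t in v}
        | {t for v in dnr_vecs for t in v}
    )
    pos = {t: i for i, t in enumerate(vocab)}

    def dense(vec):
        arr = np.zeros(len(vocab))
        for t, w in vec.items():
            arr[pos[t]] = w
        return arr

    out = alpha * dense(qvec)
    if dr_vecs:
        out = out + beta * np.mean([dense(v) for v in dr_vecs], axis=0)
    if dnr_vecs:
        out = out - gamma * np.mean([dense(v) for v in dnr_vecs], axis=0)
    out = np.maximum(out, 0.0)
    return {t: out[pos[t]] for t in vocab}
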