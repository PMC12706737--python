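"""Congener-profile normalization and cosine similarity.

A profile is a vector of per-peak mass fractions.  Cosine similarity,
cos(theta) = a.b / (|a||b|), compares profile shape independent of
magnitude: 1.0 for identical shapes, 0.0 for disjoint congener support.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


def normalize_profile(values: pd.Series, label: str | None = None) -> pd.Series:
    """Scale nonnegative per-peak values to mass fractions summing to one."""
    v = pd.Series(values, dtype=float)
    if (v < 0).any():
        raise ValueError("profile values must be nonnegative")
    total = v.sum()
    if total <= 0:
        raise ValueError("cannot normalize an all-zero profile")
    out = v / total
    out.name = label if label is not None else getattr(values, "name", None)
    return out


def cosine_similarity(a: pd.Series, b: pd.Series) -> float:
    """cos(theta) between two profiles, in [0, 1] for nonnegative vectors.

    Profiles on different peak sets are intersected and renormalized with
    a warning.
    """
    if not a.index.equals(b.index):
        common = a.index.intersection(b.index)
        if len(common) == 0:
            raise ValueError("profiles share no peaks")
        warnings.warn(
            f"profiles on different peak sets; intersecting to {len(common)} "
            f"peaks and renormalizing", stacklevel=2)
        a = normalize_profile(a.loc[common])
        b = normalize_profile(b.loc[common])
    av, bv = a.to_numpy(float), b.to_numpy(float)
    na, nb = np.linalg.norm(av), np.linalg.norm(bv)
    if na == 0 or nb == 0:
        raise ValueError("zero-norm profile")
    return float(np.clip(av @ bv / (na * nb), 0.0, 1.0))


def profile_similarity_report(samples: dict[str, pd.Series],
                              references: dict[str, pd.Series] | None = None
                              ) -> dict:
    """Pairwise cosine-similarity matrix plus summary statistics.

    Returns the full sample-vs-sample matrix (unit diagonal), the mean and
    sd of off-diagonal pairwise cos(theta), and -- if references are given
    -- a sample-by-reference matrix with each sample's best-matching
    reference.
    """
    names = list(samples)
    if len(names) < 2:
        raise ValueError("need at least two sample profiles")
    n = len(names)
    mat = pd.DataFrame(np.eye(n), index=names, columns=names)
    pair = []
    for i in range(n):
        for j in range(i + 1, n):
            c = cosine_similarity(samples[names[i]], samples[names[j]])
            mat.iloc[i, j] = mat.iloc[j, i] = c
            pair.append(c)
    out = {
        "matrix": mat,
        "pairwise_mean": float(np.mean(pair)),
        "pairwise_sd": float(np.std(pair, ddof=1)) if len(pair) > 1 else 0.0,
    }
    if references:
        ref = pd.DataFrame(
            {rn: [cosine_similarity(samples[sn], rp) for sn in names]
             for rn, rp in references.items()}, index=names)
        out["reference_matrix"] = ref
        out["best_reference"] = ref.idxmax(axis=1)
        out["reference_mean"] = ref.mean(axis=0).to_dict()
        out["reference_sd"] = ref.std(axis=0, ddof=1).to_dict()
    return out


def mean_profile(samples: dict[str, pd.Series]) -> pd.Series:
    """Average of normalized profiles, renormalized."""
    df = pd.DataFrame({k: normalize_profile(v) for k, v in samples.items()})
    return normalize_profile(df.mean(axis=1), label="mean")
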