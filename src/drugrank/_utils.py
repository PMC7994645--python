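"""Shared numerical helpers: quantiles, seeding, multiple-testing adjustment."""

from __future__ import annotations

import hashlib

import numpy as np


def quantile(values, q):
    """Type-7 (linear interpolation) quantile over non-missing entries.

    Returns NaN when no finite value is present.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        return float("nan")
    # numpy's default interpolation is Hyndman-Fan type 7
    return float(np.quantile(x, q))


def derive_seed(master_seed: int, *tokens) -> int:
    """Stable sub-seed from a master seed and arbitrary string tokens.

    Hash-based so that results for one unit (e.g. a drug) do not depend on
    the order in which other units are processed. Always < 2**31.
    """
    h = hashlib.sha256()
    h.update(str(int(master_seed)).encode())
    for t in tokens:
        h.update(b"\x00")
        h.update(str(t).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)


def benjamini_hochberg(p):
    """Benjamini-Hochberg step-up adjusted p values.

    Standard monotone step-up procedure, capped at 1. NaNs are passed
    through and do not count toward the number of tests.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    pv = p[mask]
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[mask] = res
    return out
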