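"""Collapsed Gibbs sampling kernels.

The inner sweeps are compiled with numba when available; the pure-Python
twins execute the identical arithmetic on the identical random-number
stream, so results are bit-for-bit equal either way (only slower).
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if len(args) == 1 and callable(args[0]):
            return args[0]

        def wrap(func):
            return func

        return wrap


@njit(cache=False)
def _sweep_impl(words, docs, z, ndk, nkw, nk, alpha, beta, uniforms):
    K, V = nkw.shape
    probs = np.empty(K, dtype=np.float64)
    vbeta = V * beta
    for t in range(words.shape[0]):
        w = words[t]
        d = docs[t]
        k = z[t]
        ndk[d, k] -= 1
        nkw[k, w] -= 1
        nk[k] -= 1
        total = 0.0
        for kk in range(K):
            total += (ndk[d, kk] + alpha) * (nkw[kk, w] + beta) / (nk[kk] + vbeta)
            probs[kk] = total
        r = uniforms[t] * total
        knew = 0
        while probs[knew] < r:
            knew += 1
        z[t] = knew
        ndk[d, knew] += 1
        nkw[knew, w] += 1
        nk[knew] += 1


@njit(cache=False)
def _sweep_doc_impl(words, z, nd, phi, alpha, uniforms):
    K = nd.shape[0]
    probs = np.empty(K, dtype=np.float64)
    for t in range(words.shape[0]):
        w = words[t]
        k = z[t]
        nd[k] -= 1
        total = 0.0
        for kk in range(K):
            total += (nd[kk] + alpha) * phi[kk, w]
            probs[kk] = total
        r = uniforms[t] * total
        knew = 0
        while probs[knew] < r:
            knew += 1
        z[t] = knew
        nd[knew] += 1


def _sweep_python(words, docs, z, ndk, nkw, nk, alpha, beta, uniforms):
    K, V = nkw.shape
    probs = np.empty(K, dtype=np.float64)
    vbeta = V * beta
    for t in range(words.shape[0]):
        w = words[t]
        d = docs[t]
        k = z[t]
        ndk[d, k] -= 1
        nkw[k, w] -= 1
        nk[k] -= 1
        total = 0.0
        for kk in range(K):
            total += (ndk[d, kk] + alpha) * (nkw[kk, w] + beta) / (nk[kk] + vbeta)
            probs[kk] = total
        r = uniforms[t] * total
        knew = 0
        while probs[knew] < r:
            knew += 1
        z[t] = knew
        ndk[d, knew] += 1
        nkw[knew, w] += 1
        nk[knew] += 1


def _sweep_doc_python(words, z, nd, phi, alpha, uniforms):
    K = nd.shape[0]
    probs = np.empty(K, dtype=np.float64)
    for t in range(words.shape[0]):
        w = words[t]
        k = z[t]
        nd[k] -= 1
        total = 0.0
        for kk in range(K):
            total += (nd[kk] + alpha) * phi[kk, w]
            probs[kk] = total
        r = uniforms[t] * total
        knew = 0
        while probs[knew] < r:
            knew += 1
        z[t] = knew
        nd[knew] += 1


sweep = _sweep_impl if HAVE_NUMBA else _sweep_python
sweep_doc = _sweep_doc_impl if HAVE_NUMBA else _sweep_doc_python
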