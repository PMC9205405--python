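"""Hot loops: delta-modulator encoding and LIF network integration.

Both kernels are written in nopython-compatible form and jitted with
numba when available; otherwise the pure-Python versions run (slowly but
identically).

The LIF integrator propagates the coupled linear (current, membrane)
system exactly over each step via the analytic solution, so the state
between spikes is machine-precision regardless of dt; dt only quantizes
spike times, refractory periods and input delivery.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


@njit(cache=True)
def adm_encode_kernel(x, delta, refrac_n):
    """Asynchronous delta modulation of a sampled signal.

    Scanning in time order with running reference r (initialised to
    x[0]): emit UP when x[i] - r >= delta (then r += delta), DN when
    r - x[i] >= delta (then r -= delta). After any spike, both
    polarities are blocked for ``refrac_n`` samples. One spike at most
    per sample.

    Returns (sample indices, polarities) with polarity +1 for UP, -1
    for DN.
    """
    n = x.size
    idx = np.empty(n, dtype=np.int64)
    pol = np.empty(n, dtype=np.int8)
    k = 0
    r = x[0]
    last = -refrac_n - 1
    for i in range(n):
        if i - last < refrac_n:
            continue
        d = x[i] - r
        if d >= delta:
            idx[k] = i
            pol[k] = 1
            k += 1
            r += delta
            last = i
        elif -d >= delta:
            idx[k] = i
            pol[k] = -1
            k += 1
            r -= delta
            last = i
    return idx[:k], pol[:k]


@njit(cache=True)
def lif_kernel(
    n_steps,
    dt,
    # neuron arrays (n,)
    dm, threshold, reset, refrac_steps, tonic,
    # external connections (me,): source train, target neuron, weight,
    # per-step current decay, membrane coupling coefficient
    ext_src, ext_tgt, ext_w, ext_ds, ext_k,
    # recurrent connections (mr,)
    rec_src, rec_tgt, rec_w, rec_ds, rec_k,
    # input spikes: per-train step indices, CSR over trains
    train_steps, train_offsets,
    # membrane recording
    record_idx,
):
    n = dm.size
    me = ext_src.size
    mr = rec_src.size
    n_trains = train_offsets.size - 1

    i_ext = np.zeros(me)
    i_rec = np.zeros(mr)
    m = reset.copy()
    refrac = np.zeros(n, dtype=np.int64)
    fired_prev = np.zeros(n, dtype=np.bool_)
    contrib = np.zeros(n)
    ptr = train_offsets[:-1].copy()

    cap = 1 << 14
    out_neuron = np.empty(cap, dtype=np.int64)
    out_step = np.empty(cap, dtype=np.int64)
    n_out = 0

    nrec = record_idx.size
    traces = np.zeros((nrec, n_steps))

    for step in range(n_steps):
        # deliver external spikes scheduled at this step
        for tr in range(n_trains):
            while ptr[tr] < train_offsets[tr + 1] and \
                    train_steps[ptr[tr]] == step:
                for c in range(me):
                    if ext_src[c] == tr:
                        i_ext[c] += ext_w[c]
                ptr[tr] += 1
        # deliver recurrent spikes from the previous step
        for c in range(mr):
            if fired_prev[rec_src[c]]:
                i_rec[c] += rec_w[c]

        for j in range(n):
            contrib[j] = 0.0
        for c in range(me):
            contrib[ext_tgt[c]] += i_ext[c] * ext_k[c]
            i_ext[c] *= ext_ds[c]
        for c in range(mr):
            contrib[rec_tgt[c]] += i_rec[c] * rec_k[c]
            i_rec[c] *= rec_ds[c]

        for j in range(n):
            if refrac[j] > 0:
                refrac[j] -= 1
                m[j] = reset[j]
                fired_prev[j] = False
                continue
            m[j] = tonic[j] + (m[j] - tonic[j]) * dm[j] + contrib[j]
            if not np.isfinite(m[j]):
                return out_neuron[:n_out], out_step[:n_out], traces, j
            if m[j] >= threshold[j]:
                if n_out == cap:
                    cap *= 2
                    tmp_n = np.empty(cap, dtype=np.int64)
                    tmp_s = np.empty(cap, dtype=np.int64)
                    tmp_n[:n_out] = out_neuron
                    tmp_s[:n_out] = out_step
                    out_neuron = tmp_n
                    out_step = tmp_s
                out_neuron[n_out] = j
                out_step[n_out] = step + 1
                n_out += 1
                m[j] = reset[j]
                refrac[j] = refrac_steps[j]
                fired_prev[j] = True
            else:
                fired_prev[j] = False

        for r_i in range(nrec):
            traces[r_i, step] = m[record_idx[r_i]]

    return out_neuron[:n_out], out_step[:n_out], traces, -1
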