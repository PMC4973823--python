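"""Jitted inner loop for period-stratified group-swap chains.

The sequential checkerboard swap has a short per-step cost but the chain
needs many steps between recorded replicates to decorrelate a whole-network
statistic, so the proposal/accept/update loop is compiled with numba.  The
kernel mirrors :class:`asna.nullmodels.GroupSwapSampler` exactly in what it
conserves (row sums, column sums, stratum totals, per-period identification
patterns); the test suite asserts that the incrementally maintained
together-count matrix equals a from-scratch tally of the final matrix.

Only the fast path (swaps stratified within sampling periods, per-period-
union tallies) uses this module; everything else goes through the pure
Python sampler.
"""

from __future__ import annotations

import numpy as np

try:
    import numba as nb

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    HAVE_NUMBA = False


if HAVE_NUMBA:

    @nb.njit(cache=True)
    def _swap_once(M, strat_offsets, strat_rows, strat_cum, period_codes,
                   per_offsets, per_rows, together, x, max_proposals):
        n_rows, N = M.shape
        for _ in range(max_proposals):
            u = np.random.random()
            s = np.searchsorted(strat_cum, u)
            lo, hi = strat_offsets[s], strat_offsets[s + 1]
            span = hi - lo
            r1 = strat_rows[lo + np.random.randint(span)]
            r2 = strat_rows[lo + np.random.randint(span)]
            if r1 == r2:
                continue
            c1 = 0
            c2 = 0
            for k in range(N):
                if M[r1, k] and not M[r2, k]:
                    c1 += 1
                if M[r2, k] and not M[r1, k]:
                    c2 += 1
            if c1 == 0 or c2 == 0:
                continue
            pick1 = np.random.randint(c1)
            pick2 = np.random.randint(c2)
            i = -1
            j = -1
            a1 = 0
            a2 = 0
            for k in range(N):
                if M[r1, k] and not M[r2, k]:
                    if a1 == pick1:
                        i = k
                    a1 += 1
                if M[r2, k] and not M[r1, k]:
                    if a2 == pick2:
                        j = k
                    a2 += 1
            M[r1, i] = False
            M[r2, i] = True
            M[r2, j] = False
            M[r1, j] = True
            p = period_codes[r1]
            plo, phi = per_offsets[p], per_offsets[p + 1]
            for a in (i, j):
                new_t = np.zeros(N, dtype=np.bool_)
                for rr in range(plo, phi):
                    r = per_rows[rr]
                    if M[r, a]:
                        for k in range(N):
                            if M[r, k]:
                                new_t[k] = True
                new_t[a] = False
                for k in range(N):
                    d = (1 if new_t[k] else 0) - (1 if together[p, a, k] else 0)
                    if d != 0:
                        x[a, k] += d
                        x[k, a] += d
                        together[p, a, k] = new_t[k]
                        together[p, k, a] = new_t[k]
            return True
        return False

    @nb.njit(cache=True)
    def run_chain(M, strat_offsets, strat_rows, strat_cum, period_codes,
                  per_offsets, per_rows, together, x, inv_d,
                  burn_in, n_reps, thin, seed, max_proposals, weights_out):
        """Run the whole chain, recording index matrices every ``thin`` swaps.

        Returns False if proposals saturate (no valid checkerboard found).
        """
        np.random.seed(seed)
        N = M.shape[1]
        for _ in range(burn_in):
            if not _swap_once(M, strat_offsets, strat_rows, strat_cum, period_codes,
                              per_offsets, per_rows, together, x, max_proposals):
                return False
        for rep in range(n_reps):
            for _ in range(thin):
                if not _swap_once(M, strat_offsets, strat_rows, strat_cum,
                                  period_codes, per_offsets, per_rows, together, x,
                                  max_proposals):
                    return False
            for a in range(N):
                for b in range(N):
                    weights_out[rep, a, b] = x[a, b] * inv_d[a, b]
        return True
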