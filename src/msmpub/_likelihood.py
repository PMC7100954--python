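"""Closed-form likelihood for the four-state progressive model.

States: 1 Approved, 2 Completed, 3 Discontinued, 4 Published (absorbing).
Transitions are indexed 0: A->C, 1: A->D, 2: C->P, 3: D->P.  Each transition
``h`` has intensity ``lambda_h(t | x) = exp(log_baseline[h, k(t)] + x' beta[h])``
with a step-function baseline on a shared grid of cutpoints, so every
likelihood integral reduces to sums and products of exponentials of linear
functions of time and is evaluated exactly, piece by piece.

Writing ``S1(0, s | x) = exp(-L0(0,s) - L1(0,s))`` for survival in Approved
(``Lh`` the cumulative intensity of transition ``h``), the per-study
contributions are

* censored in Approved at ``c``:            ``S1(0, c)``
* intermediate transition ``m`` in ``[a,b)``, then right-censored at ``c``:
  ``int_a^b S1(0,s) lam_m(s) exp(-Lq(s, max(s, c))) ds``
* intermediate in ``[a,b)``, published in ``[p, p+1)``:
  ``int_a^b S1(0,s) lam_m(s) [exp(-Lq(s, max(s,p))) - exp(-Lq(s, p+1))] ds``

with ``q = m + 2`` the matching publication transition; exact (continuous
time) observations replace the corresponding integral by the integrand.

On each sub-piece (obtained by splitting ``[a, b)`` at the baseline
cutpoints and at the relevant absorbing bound) all intensities are
constant, and the integral of ``exp(kappa u)`` is ``delta * phi(kappa *
delta)`` with ``phi(z) = (e^z - 1)/z``.  The survival factor down to the
left end of the integration range is pulled out of the sum analytically,
so contributions remain finite in log space even for extreme parameters.

The module also provides the analytic score (gradient of the log-likelihood
in the log-baseline and covariate-effect parameters), exercised heavily by
the fitter; it is validated against numerical differentiation in the test
suite.
"""

from __future__ import annotations

import numpy as np

from .records import ObservationCase, PathType

N_TRANSITIONS = 4

_PHI_SMALL = 1e-5


def _phi(z: np.ndarray) -> np.ndarray:
    """(e^z - 1) / z, with the removable singularity at 0 filled in."""
    z = np.asarray(z, dtype=float)
    small = np.abs(z) < _PHI_SMALL
    safe = np.where(small, 1.0, z)
    with np.errstate(invalid="ignore", over="ignore"):
        out = np.expm1(safe) / safe
    return np.where(small, 1.0 + z / 2.0 + z * z / 6.0, out)


def _phi_prime(z: np.ndarray) -> np.ndarray:
    """d/dz [(e^z - 1)/z] = (e^z (z - 1) + 1) / z^2."""
    z = np.asarray(z, dtype=float)
    small = np.abs(z) < _PHI_SMALL
    safe = np.where(small, 1.0, z)
    with np.errstate(invalid="ignore", over="ignore"):
        out = (np.exp(safe) * (safe - 1.0) + 1.0) / (safe * safe)
    return np.where(small, 0.5 + z / 3.0 + z * z / 8.0, out)


class _Grid:
    """Baseline interval grid: edges [0, c_1, ..., c_K-1, inf]."""

    def __init__(self, cutpoints):
        cuts = tuple(float(c) for c in cutpoints)
        if any(c <= 0 for c in cuts) or any(
            b <= a for a, b in zip(cuts, cuts[1:])
        ):
            raise ValueError("cutpoints must be strictly increasing and positive")
        self.cutpoints = cuts
        self.edges = np.concatenate([[0.0], cuts, [np.inf]])
        self.n_intervals = len(cuts) + 1

    def interval_index(self, t: float) -> int:
        """Index of the interval containing t (right-continuous)."""
        return int(
            np.clip(
                np.searchsorted(self.edges, t, side="right") - 1,
                0,
                self.n_intervals - 1,
            )
        )

    def exposure(self, t0: float, t1: float) -> np.ndarray:
        """Overlap of [t0, t1] with each interval (clipped at 0)."""
        lo = np.maximum(self.edges[:-1], t0)
        hi = np.minimum(self.edges[1:], t1)
        return np.clip(hi - lo, 0.0, None)


def _int_group_key(m: int, kind: str) -> tuple:
    return ("int", m, kind)


def _exact_group_key(m: int, kind: str) -> tuple:
    return ("exact", m, kind)


class LikelihoodBundle:
    """Pre-compiled case structure for fast repeated likelihood evaluation.

    All parameter-independent geometry (piece decompositions, exposure
    tensors, design matrices) is computed once at construction; evaluating
    the log-likelihood or its gradient for new parameters is pure array
    arithmetic.
    """

    def __init__(self, cases, cutpoints, covariate_index=None):
        self.grid = _Grid(cutpoints)
        self.n_cases = len(cases)
        # which columns of the 8-dim encoded covariate row enter the model
        if covariate_index is None:
            covariate_index = list(range(8))
        self.covariate_index = list(covariate_index)
        self.n_covariates = len(self.covariate_index)

        staging: dict[tuple, dict] = {}
        self.case_slots: list[tuple] = []

        for ci, case in enumerate(cases):
            try:
                key, row = self._stage_case(case)
            except Exception as exc:  # annotate with the study index
                raise type(exc)(
                    f"case {ci} (study_id={getattr(case, 'study_id', '?')}): {exc}"
                ) from exc
            g = staging.setdefault(key, {"rows": []})
            self.case_slots.append((key, len(g["rows"])))
            g["rows"].append(row)

        self.groups = {key: self._pack_group(key, g["rows"]) for key, g in staging.items()}

    # -- construction ------------------------------------------------------

    def _x_row(self, case: ObservationCase) -> np.ndarray:
        full = case.covariates.as_array()
        return full[self.covariate_index]

    def _stage_case(self, case: ObservationCase):
        grid = self.grid
        x = self._x_row(case)
        if case.path is PathType.CENSORED_IN_APPROVED:
            c = float(case.absorbing_upper)
            return ("approved",), {"x": x, "E0": grid.exposure(0.0, c)}
        if case.path is PathType.UNPUBLISHED_UNKNOWN:
            c = float(case.absorbing_upper)
            if c <= 0.0:  # degenerate window: nothing could have happened
                return ("approved",), {"x": x, "E0": grid.exposure(0.0, c)}
            row = {
                "x": x,
                "E0": grid.exposure(0.0, c),
                "pieces0": self._build_pieces(0.0, c, c, "cens"),
                "pieces1": self._build_pieces(0.0, c, c, "cens"),
            }
            return ("unknown",), row

        m = case.initial_transition
        a = float(case.intermediate_lower)
        b = float(case.intermediate_upper)
        published = case.path in (
            PathType.COMPLETED_PUBLISHED,
            PathType.DISCONTINUED_PUBLISHED,
        )
        if published:
            if case.absorbing_exact:
                kind, qs = "epub", float(case.absorbing_lower)
            else:
                kind, qs = "ipub", float(case.absorbing_lower)
        else:
            kind, qs = "cens", float(case.absorbing_upper)

        if case.intermediate_exact:
            t = a
            row = {
                "x": x,
                "kt": grid.interval_index(t),
                "EA": grid.exposure(0.0, t),
            }
            if kind == "cens":
                row["EQ"] = grid.exposure(t, qs)
            elif kind == "epub":
                v = qs
                if v < t:
                    raise ValueError("publication time precedes intermediate time")
                row["EQ"] = grid.exposure(t, v)
                row["kv"] = grid.interval_index(v)
            else:  # interval publication
                p = qs
                row["EQ1"] = grid.exposure(t, p)
                row["EQ2"] = grid.exposure(t, p + 1.0)
            return _exact_group_key(m, kind), row

        if not b > a:
            raise ValueError(f"empty integration support [{a}, {b})")

        row = {"x": x, "pieces": self._build_pieces(a, b, qs, kind)}
        if kind == "epub":
            row["kv"] = grid.interval_index(qs)
        return _int_group_key(m, kind), row

    def _build_pieces(self, a, b, qs, kind):
        """Split [a, b) at cutpoints and the absorbing bound."""
        grid = self.grid
        points = {a, b}
        points.update(c for c in grid.cutpoints if a < c < b)
        if a < qs < b:
            points.add(qs)
        breaks = sorted(points)
        pieces = []
        for u, v in zip(breaks[:-1], breaks[1:]):
            piece = {
                "u": u,
                "delta": v - u,
                "k": grid.interval_index(u),
                "below": u < qs,
                "EA": grid.exposure(0.0, u),
                "EB1": grid.exposure(u, qs),
            }
            if kind == "ipub":
                piece["EB2"] = grid.exposure(u, qs + 1.0)
            pieces.append(piece)
        return pieces

    def _pack_group(self, key, rows):
        out = {"n": len(rows), "X": np.array([r["x"] for r in rows], dtype=float)}
        if key[0] == "approved":
            out["E0"] = np.array([r["E0"] for r in rows])
            return out
        if key[0] == "unknown":
            out["E0"] = np.array([r["E0"] for r in rows])
            out["sub0"] = self._pack_integral(
                [{"x": r["x"], "pieces": r["pieces0"]} for r in rows], "cens"
            )
            out["sub1"] = self._pack_integral(
                [{"x": r["x"], "pieces": r["pieces1"]} for r in rows], "cens"
            )
            return out
        if key[0] == "exact":
            kind = key[2]
            out["kt"] = np.array([r["kt"] for r in rows], dtype=int)
            out["EA"] = np.array([r["EA"] for r in rows])
            if kind in ("cens", "epub"):
                out["EQ"] = np.array([r["EQ"] for r in rows])
            if kind == "epub":
                out["kv"] = np.array([r["kv"] for r in rows], dtype=int)
            if kind == "ipub":
                out["EQ1"] = np.array([r["EQ1"] for r in rows])
                out["EQ2"] = np.array([r["EQ2"] for r in rows])
            return out
        kind = key[2]
        packed = self._pack_integral(rows, kind)
        if kind == "epub":
            packed["kv"] = np.array([r["kv"] for r in rows], dtype=int)
        return packed

    def _pack_integral(self, rows, kind):
        """Pad each case's pieces to the group maximum, repeating the last
        piece with zero width so all terms stay finite."""
        K = self.grid.n_intervals
        n = len(rows)
        out = {"n": n, "X": np.array([r["x"] for r in rows], dtype=float)}
        J = max(len(r["pieces"]) for r in rows)
        delta = np.zeros((n, J))
        kp = np.zeros((n, J), dtype=int)
        below = np.zeros((n, J), dtype=bool)
        EA = np.zeros((n, J, K))
        EB1 = np.zeros((n, J, K))
        EB2 = np.zeros((n, J, K)) if kind == "ipub" else None
        for i, r in enumerate(rows):
            ps = r["pieces"]
            for j in range(J):
                p = ps[min(j, len(ps) - 1)]
                if j < len(ps):
                    delta[i, j] = p["delta"]
                kp[i, j] = p["k"]
                below[i, j] = p["below"] and j < len(ps)
                EA[i, j] = p["EA"]
                EB1[i, j] = p["EB1"]
                if kind == "ipub":
                    EB2[i, j] = p["EB2"]
        out.update(delta=delta, kp=kp, below=below, EA=EA, EB1=EB1)
        if kind == "ipub":
            out["EB2"] = EB2
        return out

    # -- evaluation --------------------------------------------------------

    def _rates(self, group, log_baseline, beta):
        """Per-transition frailty factors e and baseline weights w."""
        w = np.exp(log_baseline)  # (4, K)
        eta = group["X"] @ beta.T  # (n, 4)
        e = np.exp(eta)
        return w, e

    def per_case_loglik(self, log_baseline, beta) -> np.ndarray:
        """Log-likelihood contribution of every case, in input order."""
        per_group = {
            key: self._group_eval(key, g, log_baseline, beta, want_grad=False)[0]
            for key, g in self.groups.items()
        }
        out = np.empty(self.n_cases)
        for i, (key, pos) in enumerate(self.case_slots):
            out[i] = per_group[key][pos]
        return out

    def loglik(self, log_baseline, beta) -> float:
        total = 0.0
        for key, g in self.groups.items():
            ll, _, _ = self._group_eval(key, g, log_baseline, beta, want_grad=False)
            total += float(ll.sum())
        return total

    def loglik_and_grad(self, log_baseline, beta):
        """Total log-likelihood with its gradient in (log_baseline, beta)."""
        K = self.grid.n_intervals
        P = self.n_covariates
        total = 0.0
        g_lb = np.zeros((N_TRANSITIONS, K))
        g_beta = np.zeros((N_TRANSITIONS, P))
        for key, g in self.groups.items():
            ll, d_lb, d_beta = self._group_eval(key, g, log_baseline, beta, want_grad=True)
            total += float(ll.sum())
            g_lb += d_lb
            g_beta += d_beta
        return total, g_lb, g_beta

    def _group_eval(self, key, g, log_baseline, beta, want_grad):
        # extreme parameter proposals during optimization can overflow
        # intermediate factors; the resulting non-finite objective is
        # rejected by the caller, so the warnings carry no information
        with np.errstate(all="ignore"):
            if key[0] == "approved":
                return self._eval_approved(g, log_baseline, beta, want_grad)
            if key[0] == "unknown":
                return self._eval_unknown(g, log_baseline, beta, want_grad)
            if key[0] == "exact":
                return self._eval_exact(key, g, log_baseline, beta, want_grad)
            return self._eval_integral(key, g, log_baseline, beta, want_grad)

    def _eval_approved(self, g, log_baseline, beta, want_grad, case_weights=None):
        w, e = self._rates(g, log_baseline, beta)
        L0 = (g["E0"] @ w[0]) * e[:, 0]
        L1 = (g["E0"] @ w[1]) * e[:, 1]
        ll = -(L0 + L1)
        if not want_grad:
            return ll, None, None
        wt = np.ones(g["n"]) if case_weights is None else case_weights
        K, P = self.grid.n_intervals, self.n_covariates
        g_lb = np.zeros((N_TRANSITIONS, K))
        g_beta = np.zeros((N_TRANSITIONS, P))
        for t, Lt in ((0, L0), (1, L1)):
            g_beta[t] = -(g["X"].T @ (wt * Lt))
            g_lb[t] = -w[t] * np.einsum("i,ik->k", wt * e[:, t], g["E0"])
        return ll, g_lb, g_beta

    def _eval_unknown(self, g, log_baseline, beta, want_grad):
        """Unpublished, state unknown: P(no publication by c) mixes the
        still-Approved, completed-unpublished and discontinued-unpublished
        contributions; gradients combine the components with their
        posterior weights."""
        ll1 = self._eval_approved(g, log_baseline, beta, False)[0]
        ll2 = self._eval_integral(("int", 0, "cens"), g["sub0"], log_baseline, beta, False)[0]
        ll3 = self._eval_integral(("int", 1, "cens"), g["sub1"], log_baseline, beta, False)[0]
        M = np.maximum(ll1, np.maximum(ll2, ll3))
        M = np.where(np.isfinite(M), M, 0.0)
        e1, e2, e3 = np.exp(ll1 - M), np.exp(ll2 - M), np.exp(ll3 - M)
        S = e1 + e2 + e3
        ll = M + np.log(S)
        if not want_grad:
            return ll, None, None
        _, glb1, gb1 = self._eval_approved(g, log_baseline, beta, True, case_weights=e1 / S)
        _, glb2, gb2 = self._eval_integral(
            ("int", 0, "cens"), g["sub0"], log_baseline, beta, True, case_weights=e2 / S
        )
        _, glb3, gb3 = self._eval_integral(
            ("int", 1, "cens"), g["sub1"], log_baseline, beta, True, case_weights=e3 / S
        )
        return ll, glb1 + glb2 + glb3, gb1 + gb2 + gb3

    def _eval_exact(self, key, g, log_baseline, beta, want_grad):
        _, m, kind = key
        o, q = 1 - m, m + 2
        w, e = self._rates(g, log_baseline, beta)
        X = g["X"]
        eta = X @ beta.T
        Am = (g["EA"] @ w[m]) * e[:, m]
        Ao = (g["EA"] @ w[o]) * e[:, o]
        ll = log_baseline[m][g["kt"]] + eta[:, m] - Am - Ao
        if kind in ("cens", "epub"):
            Q = (g["EQ"] @ w[q]) * e[:, q]
            ll = ll - Q
            if kind == "epub":
                ll = ll + log_baseline[q][g["kv"]] + eta[:, q]
        else:  # ipub
            Q1 = (g["EQ1"] @ w[q]) * e[:, q]
            dQ = (g["EQ2"] @ w[q]) * e[:, q] - Q1
            with np.errstate(divide="ignore"):
                ll = ll - Q1 + np.log(-np.expm1(-dQ))
        if not want_grad:
            return ll, None, None

        K, P = self.grid.n_intervals, self.n_covariates
        g_lb = np.zeros((N_TRANSITIONS, K))
        g_beta = np.zeros((N_TRANSITIONS, P))
        g_beta[m] = X.T @ (1.0 - Am)
        g_beta[o] = X.T @ (-Ao)
        g_lb[m] = np.bincount(g["kt"], minlength=K) - w[m] * np.einsum(
            "i,ik->k", e[:, m], g["EA"]
        )
        g_lb[o] = -w[o] * np.einsum("i,ik->k", e[:, o], g["EA"])
        if kind in ("cens", "epub"):
            g_beta[q] = X.T @ (-Q)
            g_lb[q] = -w[q] * np.einsum("i,ik->k", e[:, q], g["EQ"])
            if kind == "epub":
                g_beta[q] += X.sum(axis=0)
                g_lb[q] += np.bincount(g["kv"], minlength=K)
        else:
            # d/d. of log(exp(-Q1) - exp(-Q2)) with dQ = Q2 - Q1 > 0
            with np.errstate(divide="ignore", over="ignore"):
                inv = -1.0 / np.expm1(-dQ)  # = R1 / S
            r2s = inv * np.exp(-dQ)  # = R2 / S
            Q2 = Q1 + dQ
            g_beta[q] = X.T @ (-Q1 * inv + Q2 * r2s)
            g_lb[q] = -w[q] * (
                np.einsum("i,ik->k", e[:, q] * inv, g["EQ1"])
                - np.einsum("i,ik->k", e[:, q] * r2s, g["EQ2"])
            )
        return ll, g_lb, g_beta

    def _eval_integral(self, key, g, log_baseline, beta, want_grad, case_weights=None):
        _, m, kind = key
        o, q = 1 - m, m + 2
        w, e = self._rates(g, log_baseline, beta)
        X, kp, delta, below = g["X"], g["kp"], g["delta"], g["below"]
        eta = X @ beta.T

        rm = w[m][kp] * e[:, m, None]
        ro = w[o][kp] * e[:, o, None]
        rq = w[q][kp] * e[:, q, None]
        ra = rm + ro

        Am = np.einsum("ijk,k->ij", g["EA"], w[m]) * e[:, m, None]
        Ao = np.einsum("ijk,k->ij", g["EA"], w[o]) * e[:, o, None]
        A = Am + Ao
        B1 = np.einsum("ijk,k->ij", g["EB1"], w[q]) * e[:, q, None]

        z1 = (np.where(below, rq, 0.0) - ra) * delta
        F1 = np.exp(-B1) * delta * _phi(z1)
        if kind == "ipub":
            B2 = np.einsum("ijk,k->ij", g["EB2"], w[q]) * e[:, q, None]
            z2 = (rq - ra) * delta
            F2 = np.exp(-B2) * delta * _phi(z2)
        else:
            B2 = None
            F2 = np.zeros_like(F1)
        D = F1 - F2

        A0 = A[:, 0]
        T = rm * np.exp(-(A - A0[:, None])) * D
        L = T.sum(axis=1)
        with np.errstate(divide="ignore"):
            ll = -A0 + np.log(L)
        if kind == "epub":
            ll = ll + log_baseline[q][g["kv"]] + eta[:, q]
        if not want_grad:
            return ll, None, None

        wt = np.ones(g["n"]) if case_weights is None else case_weights
        K, P = self.grid.n_intervals, self.n_covariates
        g_lb = np.zeros((N_TRANSITIONS, K))
        g_beta = np.zeros((N_TRANSITIONS, P))

        safeL = np.where(L > 0, L, 1.0)
        W = T / safeL[:, None]
        V = rm * np.exp(-(A - A0[:, None])) / safeL[:, None]  # = W / D

        G1 = np.exp(-B1) * delta * delta * _phi_prime(z1)
        if kind == "ipub":
            G2 = np.exp(-B2) * delta * delta * _phi_prime(z2)
        else:
            G2 = np.zeros_like(G1)

        # covariate effects ------------------------------------------------
        s_m = (W * (1.0 - Am) + V * rm * (G2 - G1)).sum(axis=1)
        s_o = (-W * Ao + V * ro * (G2 - G1)).sum(axis=1)
        bracket_q = -F1 * B1
        if kind == "ipub":
            bracket_q = bracket_q + F2 * B2
        bracket_q = bracket_q + np.where(below, G1 * rq, 0.0) - G2 * rq
        s_q = (V * bracket_q).sum(axis=1)
        if kind == "epub":
            s_q = s_q + 1.0
        g_beta[m] = X.T @ (wt * s_m)
        g_beta[o] = X.T @ (wt * s_o)
        g_beta[q] = X.T @ (wt * s_q)

        # baseline levels ---------------------------------------------------
        Wg = W * wt[:, None]
        Vg = V * wt[:, None]
        flat = kp.ravel()
        g_lb[m] = np.bincount(
            flat, weights=(Wg + Vg * rm * (G2 - G1)).ravel(), minlength=K
        ) - w[m] * np.einsum("i,ij,ijk->k", wt * e[:, m], W, g["EA"])
        g_lb[o] = np.bincount(
            flat, weights=(Vg * ro * (G2 - G1)).ravel(), minlength=K
        ) - w[o] * np.einsum("i,ij,ijk->k", wt * e[:, o], W, g["EA"])
        gq = np.bincount(
            flat,
            weights=(Vg * (np.where(below, G1 * rq, 0.0) - G2 * rq)).ravel(),
            minlength=K,
        )
        gq = gq - w[q] * np.einsum("i,ij,ijk->k", wt * e[:, q], V * F1, g["EB1"])
        if kind == "ipub":
            gq = gq + w[q] * np.einsum("i,ij,ijk->k", wt * e[:, q], V * F2, g["EB2"])
        if kind == "epub":
            gq = gq + np.bincount(g["kv"], weights=wt, minlength=K)
        g_lb[q] = gq
        return ll, g_lb, g_beta
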