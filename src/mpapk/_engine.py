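"""Vectorised numerical kernels behind estimation, diagnostics and simulation.

Everything here works on packed rectangular arrays so that one call evaluates
the model for a whole cohort — and, during fitting, for a whole batch of
candidate population-parameter vectors at once (the outer finite-difference
gradient is a single batched call).  Shapes follow the convention

    B : batch of population-parameter vectors
    S : subjects
    T : observation grid (padded, with a mask)
    D : dose events (padded with zero amounts)

and the parameter axis is always ordered ``(ka, V, V2, CL, Q, Tlag)``.

The conditional-mode (empirical Bayes) search flattens the B x S pairs and
iterates a damped Newton step on the shrinking set of unconverged pairs; the
model Jacobian with respect to the log-scale random effects is analytic
(chain rule through the hybrid rate constants), so one iteration costs one
closed-form model evaluation plus cheap recombinations of its exponentials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import Dataset

F_FLOOR = 1e-12  # floor on predicted concentration inside the variance model
OMEGA_FLOOR = 1e-10  # variance floor that pins eta to ~0 when omega^2 == 0
ETA_CLIP = 20.0  # |eta| bound during the mode search
# Width (h) of the C1 smoothing of the absorption-onset kink used inside the
# likelihood kernels.  An individual lag time can sit exactly on a sampling
# time, where the exact model's Jacobian is discontinuous and conditional
# estimation jumps; an ~18-second smoothstep makes the objective
# differentiable while perturbing predictions by less than the assay floor
# except within the smoothing window itself.
SMOOTH_LAG = 0.005
_EYE6 = np.eye(6)


def _smoothstep(tau, width):
    """C1 ramp 0 -> 1 over [0, width] (hard indicator when width == 0)."""
    if width <= 0.0:
        return (tau > 0.0).astype(float), None
    u = np.clip(tau / width, 0.0, 1.0)
    s = u * u * (3.0 - 2.0 * u)
    ds_dtau = 6.0 * u * (1.0 - u) / width
    return s, ds_dtau


@dataclass
class PackedData:
    """A cohort flattened to rectangular arrays (padded + masked)."""

    subject_ids: list
    y: np.ndarray  # (S, T) observed concentrations
    mask: np.ndarray  # (S, T) True where a usable observation exists
    times: np.ndarray  # (S, T) absolute hours since first dose
    dose_t: np.ndarray  # (S, D)
    dose_amt: np.ndarray  # (S, D), zero-padded
    covariates: dict  # name -> (S,)
    n_obs: np.ndarray  # (S,)

    @property
    def n_subjects(self) -> int:
        return self.y.shape[0]


def pack_dataset(dataset: Dataset, blq_rule: str = "discard") -> PackedData:
    """Flatten a Dataset for the vectorised kernels.

    ``blq_rule``: 'discard' drops BLQ observations (M1), 'half-lloq' imputes
    LLOQ/2, 'flag-only' keeps the recorded value.
    """
    if blq_rule not in ("discard", "half-lloq", "flag-only"):
        raise ValueError(f"unknown BLQ rule {blq_rule!r}")
    per_subject = []
    for s in dataset.subjects:
        t, dv, blq = s.observation_arrays()
        if blq_rule == "discard":
            keep = ~blq
            t, dv = t[keep], dv[keep]
        elif blq_rule == "half-lloq":
            dv = np.where(blq, dataset.lloq / 2.0, dv)
        per_subject.append((s, t, dv))

    S = len(per_subject)
    T = max((len(t) for _, t, _ in per_subject), default=0)
    D = max(len(s.doses) for s, _, _ in per_subject)
    y = np.zeros((S, T))
    mask = np.zeros((S, T), dtype=bool)
    times = np.zeros((S, T))
    dose_t = np.zeros((S, D))
    dose_amt = np.zeros((S, D))
    cov_names = sorted({name for s, _, _ in per_subject for name in s.covariates})
    covariates = {name: np.zeros(S) for name in cov_names}
    for i, (s, t, dv) in enumerate(per_subject):
        n = len(t)
        y[i, :n] = dv
        mask[i, :n] = True
        times[i, :n] = t
        dose_t[i, : len(s.doses)] = [d.time for d in s.doses]
        dose_amt[i, : len(s.doses)] = [d.amount for d in s.doses]
        for name in cov_names:
            covariates[name][i] = s.covariates.get(name, np.nan)
    return PackedData(
        subject_ids=[s.subject_id for s, _, _ in per_subject],
        y=y,
        mask=mask,
        times=times,
        dose_t=dose_t,
        dose_amt=dose_amt,
        covariates=covariates,
        n_obs=mask.sum(axis=1),
    )


def conc_batch(params: np.ndarray, times: np.ndarray, dose_t: np.ndarray,
               dose_amt: np.ndarray, smooth: float = 0.0) -> np.ndarray:
    """Closed-form concentration for batched parameter sets.

    params : (..., S, 6) in canonical order; times (..., S, T); doses (S, D).
    Returns concentrations of shape (..., S, T).  ``smooth`` > 0 replaces the
    hard absorption-onset indicator by a smoothstep of that width (used only
    inside the estimation kernels).
    """
    ka = params[..., 0]
    V = params[..., 1]
    Tlag = params[..., 5]
    alpha, beta, k21 = _hybrid_rates(params)
    ka = _nudge_ka(ka, alpha, beta)
    A, Bc, C = _macro_coefficients(ka, alpha, beta, k21)

    tau = times[..., :, :, None] - dose_t[..., :, None, :] - Tlag[..., None, None]
    active, _ = _smoothstep(tau, smooth)
    tau = np.maximum(tau, 0.0)
    shape = (
        A[..., None, None] * np.exp(-alpha[..., None, None] * tau)
        + Bc[..., None, None] * np.exp(-beta[..., None, None] * tau)
        + C[..., None, None] * np.exp(-ka[..., None, None] * tau)
    )
    contrib = dose_amt[..., :, None, :] * shape * active
    return (ka / V)[..., None] * contrib.sum(axis=-1)


def _hybrid_rates(params):
    V = params[..., 1]
    V2 = params[..., 2]
    CL = params[..., 3]
    Q = params[..., 4]
    k10 = CL / V
    k12 = Q / V
    k21 = Q / V2
    s = k10 + k12 + k21
    disc = np.sqrt(np.maximum(s * s - 4.0 * k10 * k21, 0.0))
    alpha = 0.5 * (s + disc)
    beta = k10 * k21 / alpha
    return alpha, beta, k21


def _nudge_ka(ka, alpha, beta):
    # removable singularity at ka == alpha or beta: 1e-7 relative nudge
    ka = np.where(np.abs(ka - alpha) < 1e-8 * ka, ka * (1.0 + 1e-7), ka)
    return np.where(np.abs(ka - beta) < 1e-8 * ka, ka * (1.0 + 1e-7), ka)


def _macro_coefficients(ka, alpha, beta, k21):
    A = (k21 - alpha) / ((ka - alpha) * (beta - alpha))
    Bc = (k21 - beta) / ((ka - beta) * (alpha - beta))
    C = (k21 - ka) / ((alpha - ka) * (beta - ka))
    return A, Bc, C


def conc_and_eta_jacobian(params, times, dose_t, dose_amt, smooth=SMOOTH_LAG):
    """Concentration and its analytic Jacobian wrt the log-scale parameters.

    params : (N, 6) natural-scale individual parameters; times (N, T);
    doses (N, D).  Returns (f, J) with f (N, T) and J (N, T, 6) where
    J[..., k] = df / d eta_k = df / d p_k * p_k (lognormal chain rule).

    Derivatives chain through the hybrid exponents: with s = k10+k12+k21 and
    P = k10 k21, d(alpha) = (alpha ds - dP) / (alpha - beta) and
    d(beta) = ds - d(alpha); the macro coefficients differentiate as
    rational functions.  All six partials reuse the same three exponential
    arrays, so the Jacobian costs little more than the evaluation itself.
    The absorption onset uses the ``smooth``-width smoothstep so the Tlag
    derivative is continuous.
    """
    ka, V, V2, CL, Q, Tlag = (params[:, k] for k in range(6))
    k10 = CL / V
    k12 = Q / V
    k21 = Q / V2
    s = k10 + k12 + k21
    disc = np.sqrt(np.maximum(s * s - 4.0 * k10 * k21, 0.0))
    alpha = 0.5 * (s + disc)
    beta = k10 * k21 / alpha
    ka = _nudge_ka(ka, alpha, beta)
    den_a = (ka - alpha) * (beta - alpha)
    den_b = (ka - beta) * (alpha - beta)
    den_c = (alpha - ka) * (beta - ka)
    A = (k21 - alpha) / den_a
    Bc = (k21 - beta) / den_b
    Cc = (k21 - ka) / den_c

    tau = times[:, :, None] - dose_t[:, None, :] - Tlag[:, None, None]
    act, dact = _smoothstep(tau, smooth)
    tau = np.maximum(tau, 0.0)
    Ea = np.exp(-alpha[:, None, None] * tau) * act
    Eb = np.exp(-beta[:, None, None] * tau) * act
    Ek = np.exp(-ka[:, None, None] * tau) * act

    amt = dose_amt[:, None, :]
    Wa = (amt * Ea).sum(-1)  # (N, T) dose-weighted exponential sums
    Wb = (amt * Eb).sum(-1)
    Wk = (amt * Ek).sum(-1)
    Ta = (amt * tau * Ea).sum(-1)
    Tb = (amt * tau * Eb).sum(-1)
    Tk = (amt * tau * Ek).sum(-1)
    if dact is not None:
        # onset-ramp derivative term: sum of amt * base * d(act)/d(tau)
        base_unact = (
            A[:, None, None] * np.exp(-alpha[:, None, None] * tau)
            + Bc[:, None, None] * np.exp(-beta[:, None, None] * tau)
            + Cc[:, None, None] * np.exp(-ka[:, None, None] * tau)
        )
        Wramp = (amt * base_unact * dact).sum(-1)
    else:
        Wramp = 0.0

    pref = ka / V
    f = pref[:, None] * (A[:, None] * Wa + Bc[:, None] * Wb + Cc[:, None] * Wk)

    J = np.empty(f.shape + (6,))

    ab = alpha - beta

    def coeff_partials(dk21, d_alpha, d_beta):
        """(dA, dB, dC) for a parameter that moves k21/alpha/beta, ka fixed."""
        dden_a = -d_alpha * (beta - alpha) + (ka - alpha) * (d_beta - d_alpha)
        dA = ((dk21 - d_alpha) - A * dden_a) / den_a
        dden_b = -d_beta * (alpha - beta) + (ka - beta) * (d_alpha - d_beta)
        dB = ((dk21 - d_beta) - Bc * dden_b) / den_b
        dden_c = d_alpha * (beta - ka) + (alpha - ka) * d_beta
        dC = (dk21 - Cc * dden_c) / den_c
        return dA, dB, dC

    def structural(dA, dB, dC, d_alpha, d_beta, dpref_over_pref):
        """df/dp for ka-independent p, assembled from the weighted sums."""
        out = (
            dA[:, None] * Wa + dB[:, None] * Wb + dC[:, None] * Wk
            - (A * d_alpha)[:, None] * Ta - (Bc * d_beta)[:, None] * Tb
        )
        return pref[:, None] * out + dpref_over_pref[:, None] * f

    zero = np.zeros_like(ka)
    # --- V ---
    dk10, dk12, dk21 = -CL / V**2, -Q / V**2, zero
    ds, dP = dk10 + dk12 + dk21, dk10 * k21 + k10 * dk21
    d_alpha = (alpha * ds - dP) / ab
    d_beta = ds - d_alpha
    dA, dB, dC = coeff_partials(dk21, d_alpha, d_beta)
    J[..., 1] = structural(dA, dB, dC, d_alpha, d_beta, -1.0 / V) * V[:, None]
    # --- V2 ---
    dk21 = -Q / V2**2
    ds, dP = dk21, k10 * dk21
    d_alpha = (alpha * ds - dP) / ab
    d_beta = ds - d_alpha
    dA, dB, dC = coeff_partials(dk21, d_alpha, d_beta)
    J[..., 2] = structural(dA, dB, dC, d_alpha, d_beta, zero) * V2[:, None]
    # --- CL ---
    dk10, dk21 = 1.0 / V, zero
    ds, dP = dk10, dk10 * k21
    d_alpha = (alpha * ds - dP) / ab
    d_beta = ds - d_alpha
    dA, dB, dC = coeff_partials(dk21, d_alpha, d_beta)
    J[..., 3] = structural(dA, dB, dC, d_alpha, d_beta, zero) * CL[:, None]
    # --- Q ---
    dk12, dk21 = 1.0 / V, 1.0 / V2
    ds, dP = dk12 + dk21, k10 * dk21
    d_alpha = (alpha * ds - dP) / ab
    d_beta = ds - d_alpha
    dA, dB, dC = coeff_partials(dk21, d_alpha, d_beta)
    J[..., 4] = structural(dA, dB, dC, d_alpha, d_beta, zero) * Q[:, None]
    # --- ka ---  (alpha, beta, k21 fixed; E_k depends on ka)
    dA = -A / (ka - alpha)
    dB = -Bc / (ka - beta)
    dC = (-1.0 + Cc * ((beta - ka) + (alpha - ka))) / den_c
    dfdka = pref[:, None] * (
        dA[:, None] * Wa + dB[:, None] * Wb + dC[:, None] * Wk - Cc[:, None] * Tk
    ) + f / ka[:, None]
    J[..., 0] = dfdka * ka[:, None]
    # --- Tlag ---  d tau / d Tlag = -1 for every dose term
    J[..., 5] = (
        pref[:, None]
        * ((A * alpha)[:, None] * Wa + (Bc * beta)[:, None] * Wb
           + (Cc * ka)[:, None] * Wk - Wramp)
        * Tlag[:, None]
    )
    return f, J


@dataclass
class _FlatProblem:
    """B x S pairs flattened to one axis for the mode search."""

    typ: np.ndarray  # (N, 6)
    om2inv: np.ndarray  # (N, 6)
    sig: np.ndarray  # (N,)
    times: np.ndarray  # (N, T)
    dose_t: np.ndarray  # (N, D)
    dose_amt: np.ndarray  # (N, D)
    y: np.ndarray  # (N, T)
    mask: np.ndarray  # (N, T)


def _flatten(typ, omega2, sigma, packed: PackedData) -> _FlatProblem:
    B, S = typ.shape[0], typ.shape[1]
    T, D = packed.y.shape[1], packed.dose_t.shape[1]
    om2inv = np.broadcast_to(
        (1.0 / np.maximum(omega2, OMEGA_FLOOR))[:, None, :], (B, S, 6)
    ).reshape(-1, 6)
    return _FlatProblem(
        typ=typ.reshape(-1, 6),
        om2inv=om2inv,
        sig=np.broadcast_to(sigma[:, None], (B, S)).reshape(-1),
        times=np.broadcast_to(packed.times[None], (B, S, T)).reshape(-1, T),
        dose_t=np.broadcast_to(packed.dose_t[None], (B, S, D)).reshape(-1, D),
        dose_amt=np.broadcast_to(packed.dose_amt[None], (B, S, D)).reshape(-1, D),
        y=np.broadcast_to(packed.y[None], (B, S, T)).reshape(-1, T),
        mask=np.broadcast_to(packed.mask[None], (B, S, T)).reshape(-1, T),
    )


def _flat_neg2ll(fp: _FlatProblem, idx, eta, f):
    """-2 log joint density of (y, eta) for the flat pairs in ``idx``."""
    fsafe = np.maximum(f, F_FLOOR)
    var = (fp.sig[idx, None] * fsafe) ** 2
    r = fp.y[idx] - f
    ll = fp.mask[idx] * (r * r / var + np.log(2.0 * np.pi * var))
    return ll.sum(axis=-1) + (eta * eta * fp.om2inv[idx]).sum(axis=-1)


def _flat_conc(fp: _FlatProblem, idx, eta):
    params = fp.typ[idx] * np.exp(eta)
    return conc_batch(params[None], fp.times[idx], fp.dose_t[idx],
                      fp.dose_amt[idx], smooth=SMOOTH_LAG)[0]


def eval_with_jacobian(typ, eta, packed: PackedData, smooth=SMOOTH_LAG):
    """Model values and eta-Jacobians for given etas, shaped (B, S, ...)."""
    B, S = typ.shape[0], typ.shape[1]
    T, D = packed.y.shape[1], packed.dose_t.shape[1]
    params = (typ * np.exp(eta)).reshape(-1, 6)
    times = np.broadcast_to(packed.times[None], (B, S, T)).reshape(-1, T)
    dose_t = np.broadcast_to(packed.dose_t[None], (B, S, D)).reshape(-1, D)
    dose_amt = np.broadcast_to(packed.dose_amt[None], (B, S, D)).reshape(-1, D)
    f, J = conc_and_eta_jacobian(params, times, dose_t, dose_amt, smooth=smooth)
    return f.reshape(B, S, T), J.reshape(B, S, T, 6)


def map_etas(typ, omega2, sigma, packed: PackedData, eta0=None,
             max_iter=60, step_tol=1e-8, grad_tol=1e-4):
    """Conditional modes of the random effects (empirical Bayes / MAP).

    typ : (B, S, 6) typical parameters after covariates
    omega2 : (B, 6) diagonal IIV variances; sigma : (B,) proportional sd.
    Returns (eta, f, J, q): modes, model values, eta-Jacobians at the modes
    and the -2 log joint density there, shaped (B, S, ...).

    Damped Newton (Gauss-Newton Hessian + exact gradient of the interaction
    variance term) with per-pair Levenberg damping, iterating only the pairs
    that have not yet converged.  Deterministic given ``eta0``.
    """
    B, S = typ.shape[0], typ.shape[1]
    N = B * S
    fp = _flatten(typ, omega2, sigma, packed)
    eta = (np.zeros((N, 6)) if eta0 is None
           else np.asarray(eta0, dtype=float).reshape(N, 6).copy())

    with np.errstate(all="ignore"):
        q = _flat_neg2ll(fp, slice(None), eta, _flat_conc(fp, slice(None), eta))
        lam = np.full(N, 1e-3)
        act = np.arange(N)
        for _ in range(max_iter):
            if act.size == 0:
                break
            e = eta[act]
            params = fp.typ[act] * np.exp(e)
            f, J = conc_and_eta_jacobian(params, fp.times[act], fp.dose_t[act],
                                         fp.dose_amt[act])
            fsafe = np.maximum(f, F_FLOOR)
            var = (fp.sig[act, None] * fsafe) ** 2
            r = fp.y[act] - f
            m = fp.mask[act]
            w = m * (-2.0 * r / var - 2.0 * r * r / (var * fsafe) + 2.0 / fsafe)
            grad = np.einsum("ntk,nt->nk", J, w) + 2.0 * e * fp.om2inv[act]
            Jw = J * (m / var)[..., None]
            H = 2.0 * np.einsum("ntj,ntk->njk", Jw, J)
            H += 2.0 * fp.om2inv[act, :, None] * _EYE6

            step = -np.linalg.solve(
                H + lam[act, None, None] * _EYE6, grad[..., None]
            )[..., 0]
            e_new = np.clip(e + step, -ETA_CLIP, ETA_CLIP)
            q_new = _flat_neg2ll(fp, act, e_new, _flat_conc(fp, act, e_new))
            q_prev = q[act]
            accept = np.isfinite(q_new) & (q_new <= q_prev)
            eta[act] = np.where(accept[:, None], e_new, e)
            q[act] = np.where(accept, q_new, q_prev)
            lam[act] = np.where(accept, np.maximum(lam[act] * 0.2, 1e-10),
                                lam[act] * 8.0)
            step_size = np.abs(step).max(axis=-1)
            grad_size = np.abs(grad).max(axis=-1)
            stalled = accept & (q_prev - q_new < 1e-9) & (step_size < 1e-3)
            done = ((accept & (step_size < step_tol))
                    | (grad_size < grad_tol)
                    | (~accept & (lam[act] > 1e8))
                    | stalled)
            act = act[~done]

        params = fp.typ * np.exp(eta)
        f, J = conc_and_eta_jacobian(params, fp.times, fp.dose_t, fp.dose_amt)
        q = _flat_neg2ll(fp, slice(None), eta, f)
    T = packed.y.shape[1]
    return (eta.reshape(B, S, 6), f.reshape(B, S, T),
            J.reshape(B, S, T, 6), q.reshape(B, S))


def map_etas_best(typ, omega2, sigma, packed: PackedData, starts,
                  max_iter=120):
    """Run the mode search from several starts, keep each subject's best mode.

    ``starts`` is an iterable of (B, S, 6) arrays (or None for zeros).
    """
    best = None
    for eta0 in starts:
        eta, f, J, q = map_etas(typ, omega2, sigma, packed, eta0=eta0,
                                max_iter=max_iter)
        if best is None:
            best = [eta, f, J, q]
        else:
            better = q < best[3]
            best[0] = np.where(better[..., None], eta, best[0])
            best[1] = np.where(better[..., None], f, best[1])
            best[2] = np.where(better[..., None, None], J, best[2])
            best[3] = np.where(better, q, best[3])
    return tuple(best)


def foce_ofv_terms(eta, f, J, typ, omega2, sigma, packed: PackedData):
    """Per-subject FOCE-with-interaction -2 log-likelihood contributions.

    Linearises the model around the conditional modes: y ~ N(f - G eta_hat,
    V) with V = G Omega G' + R, R = diag((sigma * f_hat)^2).  The diagonal
    Omega lets the determinant and quadratic form go through the 6x6
    Woodbury complement instead of the full T x T covariance.
    Returns an array of shape (B, S).
    """
    y, mask = packed.y, packed.mask
    B, S = f.shape[0], f.shape[1]
    sig = np.broadcast_to(sigma[:, None], (B, S))
    fsafe = np.maximum(f, F_FLOOR)
    var = (sig[..., None] * fsafe) ** 2
    Rinv = mask / var
    sqrt_om = np.sqrt(np.maximum(omega2, 0.0))[:, None, :]  # (B,1,6)

    GtRG = np.einsum("bstj,bst,bstk->bsjk", J, Rinv, J)
    M = _EYE6 + sqrt_om[..., :, None] * GtRG * sqrt_om[..., None, :]
    chol = np.linalg.cholesky(M)
    logdet_M = 2.0 * np.log(np.einsum("...ii->...i", chol)).sum(axis=-1)

    r = (y - f + np.einsum("bstk,bsk->bst", J, eta)) * mask
    a = Rinv * r
    b = np.einsum("bstk,bst->bsk", J, a) * sqrt_om
    sol = np.linalg.solve(M, b[..., None])[..., 0]
    quad = (r * a).sum(axis=-1) - (b * sol).sum(axis=-1)
    logdet_R = (mask * np.log(np.where(mask, var, 1.0))).sum(axis=-1)
    return logdet_R + logdet_M + quad + packed.n_obs * np.log(2.0 * np.pi)


def cwres_batch(eta, f, J, omega2, sigma, packed: PackedData):
    """Conditional weighted residuals under the FOCE linearisation (S, T)."""
    y, mask = packed.y, packed.mask
    sig = np.broadcast_to(sigma[:, None], f.shape[:2])
    fsafe = np.maximum(f, F_FLOOR)
    var = (sig[..., None] * fsafe) ** 2
    S, T = f.shape[1], f.shape[2]
    om = np.maximum(omega2, 0.0)
    cwres = np.zeros((S, T))
    for i in range(S):
        m = mask[i]
        G = J[0, i][m]  # (n, 6)
        V = G @ np.diag(om[0]) @ G.T + np.diag(var[0, i][m])
        L = np.linalg.cholesky(V)
        r = y[i][m] - f[0, i][m] + G @ eta[0, i]
        cwres[i, m] = np.linalg.solve(L, r)
    return cwres
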