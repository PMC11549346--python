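"""Ideal observer: a softmax perceptron with an entropy-dependent learning rate.

The observer receives one tone at a time (one-hot over the 12-tone
alphabet) and predicts the next.  Its learning rate is not fixed but
equals the Shannon entropy of its own predictive distribution, so updates
are *precision weighted*: a confident observer barely moves, an uncertain
one moves a lot.  The model is a categorical, dynamic-learning-rate
variant of the Rescorla–Wagner rule.

Per transition t → t+1, with weight matrix W (rows index the current
tone):

    z      = x_t · W                      (pre-softmax activations)
    ŷ      = softmax(z)                   (predictive distribution)
    loss   = −Σ_i x_{t+1,i} ln ŷ_i        (cross-entropy)
    ω      = −Σ_i ŷ_i ln ŷ_i              (Shannon entropy, nats; the
                                           dynamic learning rate)
    grad   = x_tᵀ (ŷ − x_{t+1})           (∂loss/∂W; one nonzero row)
    PE     = ω · grad                     (precision-weighted prediction
                                           error, a 12×12 matrix)
    W     ← W − PE

The scalar prediction-error trajectory fed to the encoding analyses is,
by default, the Frobenius norm of PE (equivalently ω·‖ŷ − x_{t+1}‖₂,
exact because the gradient has a single nonzero row); an alternative
surprise-based scalarisation ω·(−ln ŷ[next]) is selectable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import softmax as _softmax

from .sequences import Sequence, TransitionMatrix
from .stats import bic

__all__ = [
    "ObserverState",
    "StepRecord",
    "ObserverTrace",
    "DecayFit",
    "observer_step",
    "run_observer",
    "final_weights_vs_transitions",
    "fit_decay_models",
    "bic",
]

N_TONES = 12
PE_MODES = ("entropy_weighted_norm", "entropy_weighted_surprise")


@dataclass
class ObserverState:
    """Weight matrix W (rows: current tone, columns: predicted next tone)."""

    W: np.ndarray
    t: int = 0

    @classmethod
    def uniform(cls, n: int = N_TONES) -> "ObserverState":
        """The uniform prior: every weight entry equal to 1/n."""
        return cls(W=np.full((n, n), 1.0 / n), t=0)


@dataclass
class StepRecord:
    x_t: np.ndarray
    y_hat: np.ndarray
    z: np.ndarray
    loss: float
    omega: float
    pe_matrix: np.ndarray
    pe_scalar: float
    correct: bool


@dataclass
class ObserverTrace:
    """Per-transition scalar PE, running accuracy and the trained weights."""

    pe: np.ndarray
    loss: np.ndarray
    omega: np.ndarray
    correct: np.ndarray
    accuracy: np.ndarray
    W_final: np.ndarray
    pe_mode: str = "entropy_weighted_norm"

    def __len__(self) -> int:
        return int(self.pe.size)


def _one_hot(i: int, n: int = N_TONES) -> np.ndarray:
    v = np.zeros(n)
    v[i] = 1.0
    return v


def observer_step(
    state: ObserverState,
    current_tone: int,
    next_tone: int,
    pe_mode: str = "entropy_weighted_norm",
) -> tuple[ObserverState, StepRecord]:
    """One prediction/update cycle; returns the new state and a full record."""
    n = state.W.shape[0]
    if not (0 <= current_tone < n and 0 <= next_tone < n):
        raise ValueError("tone indices must lie in [0, %d]" % (n - 1))
    if pe_mode not in PE_MODES:
        raise ValueError(f"pe_mode must be one of {PE_MODES}")

    z = state.W[current_tone].copy()  # x_t · W selects the active row
    y_hat = _softmax(z)
    omega = float(-(y_hat * np.log(y_hat)).sum())
    grad_row = y_hat.copy()
    grad_row[next_tone] -= 1.0  # ŷ − x_{t+1}
    pe_row = omega * grad_row
    loss = float(-np.log(y_hat[next_tone]))

    W_new = state.W.copy()
    W_new[current_tone] -= pe_row
    if not np.all(np.isfinite(W_new)):
        raise FloatingPointError(
            f"non-finite weights after update at transition {state.t}"
        )

    if pe_mode == "entropy_weighted_norm":
        pe_scalar = omega * float(np.linalg.norm(grad_row))
    else:
        pe_scalar = omega * loss

    pe_matrix = np.zeros_like(state.W)
    pe_matrix[current_tone] = pe_row
    rec = StepRecord(
        x_t=_one_hot(current_tone, n),
        y_hat=y_hat,
        z=z,
        loss=loss,
        omega=omega,
        pe_matrix=pe_matrix,
        pe_scalar=pe_scalar,
        correct=bool(int(np.argmax(y_hat)) == next_tone),
    )
    return ObserverState(W_new, state.t + 1), rec


def run_observer(
    seq: Sequence, pe_mode: str = "entropy_weighted_norm"
) -> ObserverTrace:
    """Train the observer over a full stream, one transition at a time.

    The trace has one entry per adjacent tone pair (length = len(seq) − 1);
    the first tone elicits no prediction error.  ``accuracy`` is the causal
    running mean of the correctness indicator.
    """
    tones = seq.tones
    if tones.size < 2:
        raise ValueError("sequence must contain at least 2 tones")
    if pe_mode not in PE_MODES:
        raise ValueError(f"pe_mode must be one of {PE_MODES}")

    n = seq.toneset.n
    W = np.full((n, n), 1.0 / n)
    m = tones.size - 1
    pe = np.empty(m)
    loss = np.empty(m)
    omega = np.empty(m)
    correct = np.empty(m, dtype=bool)

    # inlined observer_step loop (identical arithmetic) for speed
    for t in range(m):
        cur, nxt = int(tones[t]), int(tones[t + 1])
        z = W[cur]
        zs = z - z.max()
        ez = np.exp(zs)
        y_hat = ez / ez.sum()
        om = float(-(y_hat * np.log(y_hat)).sum())
        grad = y_hat.copy()
        grad[nxt] -= 1.0
        W[cur] = W[cur] - om * grad
        if not np.all(np.isfinite(W[cur])):
            raise FloatingPointError(f"non-finite weights after update at transition {t}")
        loss[t] = -np.log(y_hat[nxt])
        omega[t] = om
        correct[t] = int(np.argmax(y_hat)) == nxt
        if pe_mode == "entropy_weighted_norm":
            pe[t] = om * np.linalg.norm(grad)
        else:
            pe[t] = om * loss[t]

    accuracy = np.cumsum(correct) / np.arange(1, m + 1)
    return ObserverTrace(pe, loss, omega, correct, accuracy, W, pe_mode)


def final_weights_vs_transitions(
    trace: ObserverTrace, tm: TransitionMatrix
) -> dict:
    """Row-wise Pearson correlation of softmax(W_final) with empirical P.

    Rows with no outgoing transitions (or zero variance on either side)
    are skipped; the summary is the mean over defined rows.
    """
    W = trace.W_final
    rows = []
    skipped = []
    for i in range(W.shape[0]):
        if tm.empty_rows[i]:
            skipped.append(i)
            rows.append(np.nan)
            continue
        p_model = _softmax(W[i])
        p_emp = tm.probabilities[i]
        if p_emp.std() == 0 or p_model.std() == 0:
            skipped.append(i)
            rows.append(np.nan)
            continue
        rows.append(float(np.corrcoef(p_model, p_emp)[0, 1]))
    rows_arr = np.array(rows)
    defined = rows_arr[~np.isnan(rows_arr)]
    return {
        "row_correlations": rows_arr,
        "mean": float(defined.mean()) if defined.size else float("nan"),
        "skipped_rows": skipped,
    }


# ---------------------------------------------------------------------------
# Decay-model comparison


@dataclass
class DecayFit:
    exp_params: tuple[float, float, float]
    lin_params: tuple[float, float]
    exp_bic: float
    lin_bic: float

    @property
    def winner(self) -> str:
        return "exponential" if self.exp_bic < self.lin_bic else "linear"


def _exp_model(x: np.ndarray, a: float, b: float, c: float) -> np.ndarray:
    return a * np.exp(-b * x) + c


def fit_decay_models(
    pe: np.ndarray, n_restarts: int = 100, seed: int = 0
) -> DecayFit:
    """Fit y = a·e^(−bx) + c and a line to a trajectory; compare by BIC.

    The exponential is fitted by unbounded nonlinear least squares with
    ``n_restarts`` random initialisations (the best RSS wins); the line in
    closed form.  x runs 1…len(pe).  BIC uses k = 3 (exponential) and
    k = 2 (linear) mean-function parameters.
    """
    y = np.asarray(pe, dtype=float)
    if y.size <= 4:
        raise ValueError("trajectory too short to compare decay models")
    x = np.arange(1, y.size + 1, dtype=float)
    rng = np.random.default_rng(seed)

    best_rss = np.inf
    best_params: tuple[float, float, float] | None = None
    span = max(y.max() - y.min(), 1e-12)
    failures = []
    for _ in range(n_restarts):
        p0 = (
            float(rng.normal(span, span)),
            float(rng.uniform(1e-4, 10.0 / y.size)),
            float(rng.normal(y.mean(), y.std() + 1e-12)),
        )
        try:
            popt, _ = curve_fit(_exp_model, x, y, p0=p0, maxfev=5000)
        except (RuntimeError, FloatingPointError, ValueError) as exc:
            failures.append(str(exc))
            continue
        resid = y - _exp_model(x, *popt)
        # floor guards the degenerate perfect fit (BIC needs RSS > 0)
        rss = max(float(resid @ resid), 1e-12)
        if np.isfinite(rss) and rss < best_rss:
            best_rss = rss
            best_params = tuple(float(p) for p in popt)
    if best_params is None:
        raise RuntimeError(
            f"exponential fit failed on all {n_restarts} restarts; "
            f"last errors: {failures[-3:]}"
        )

    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    lin_resid = y - X @ beta
    lin_rss = max(float(lin_resid @ lin_resid), 1e-12)

    return DecayFit(
        exp_params=best_params,
        lin_params=(float(beta[0]), float(beta[1])),
        exp_bic=bic(best_rss, y.size, 3),
        lin_bic=bic(lin_rss, y.size, 2),
    )
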