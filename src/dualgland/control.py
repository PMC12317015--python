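"""Adaptive loss-weight controller.

Per-loss convergence rates are tracked as an exponentially weighted moving
average of relative loss change,

    rate_t = 0.9 * rate_{t-1} + 0.1 * |L_t - L_{t-1}| / L_{t-1},

and when the two rates diverge (|rate_SG - rate_PG| > 0.3) a
proportional-integral update rebalances the weights:

    lambda(t+1) = lambda(t) * [1 + alpha_p * error(t) + alpha_i * sum(error)],
    error(t) = target_rate - rate(t),

with the per-epoch change clipped to +-max_step and the result clamped to the
weight bounds (lambda_SG in [0.3, 1.2], lambda_PG in [0.2, 0.9]).  A separate
biological constraint monitor evaluates plausibility metrics every
``monitor_interval`` epochs and can force an update when any metric drops
below its threshold.  A simpler proportional-only multiplicative rule is also
provided as an alternative controller mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass
class ControllerConfig:
    alpha_p: float = 0.05
    alpha_i: float = 0.01
    target_rate: float = 0.02
    divergence_trigger: float = 0.3
    bounds_SG: tuple = (0.3, 1.2)
    bounds_PG: tuple = (0.2, 0.9)
    max_step: float = 0.15
    ewma_old: float = 0.9
    ewma_new: float = 0.1
    monitor_interval: int = 10
    thresholds: dict = field(default_factory=lambda: {
        "boundary_definition": 0.85, "coherence": 0.80, "plausibility": 0.75})
    validation_interval: int = 5
    mode: str = "pi"  # "pi" or "p_only"

    def __post_init__(self):
        for lo, hi in (self.bounds_SG, self.bounds_PG):
            if lo >= hi:
                raise ValueError("weight bounds lo must be < hi")
        if not 0 < self.ewma_new < 1 or abs(self.ewma_old + self.ewma_new - 1) > 1e-12:
            raise ValueError("EWMA coefficients must be in (0,1) and sum to 1")


@dataclass
class ControllerState:
    lambda_SG: float = 0.75
    lambda_PG: float = 0.5
    conv_rate_SG: float = 0.0
    conv_rate_PG: float = 0.0
    integral_error_SG: float = 0.0
    integral_error_PG: float = 0.0
    prev_loss_SG: float | None = None
    prev_loss_PG: float | None = None
    epoch: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def update_convergence(rate_prev: float, L_t: float, L_prev: float,
                       cfg: ControllerConfig | None = None) -> float:
    """EWMA of relative loss change; errors if the previous loss is <= 0."""
    cfg = cfg or ControllerConfig()
    if L_prev <= 0:
        raise ValueError("previous loss must be positive")
    return cfg.ewma_old * rate_prev + cfg.ewma_new * abs(L_t - L_prev) / L_prev


def _clamped_update(lam: float, error: float, integral: float,
                    bounds: tuple, cfg: ControllerConfig) -> float:
    proposed = lam * (1.0 + cfg.alpha_p * error + cfg.alpha_i * integral)
    delta = max(-cfg.max_step, min(cfg.max_step, proposed - lam))
    return max(bounds[0], min(bounds[1], lam + delta))


def pi_step(state: ControllerState, cfg: ControllerConfig | None = None,
            force: bool = False) -> ControllerState:
    """One controller step: applies the PI update when the convergence rates
    diverge beyond the trigger (or when forced by the constraint monitor).

    Integral error accumulates only on applied steps; it is never reset when
    the trigger deactivates.  The returned state always satisfies the weight
    bounds, and per-step changes never exceed ``max_step``.
    """
    cfg = cfg or ControllerConfig()
    active = force or abs(state.conv_rate_SG - state.conv_rate_PG) > cfg.divergence_trigger
    if not active:
        state.epoch += 1
        return state
    err_sg = cfg.target_rate - state.conv_rate_SG
    err_pg = cfg.target_rate - state.conv_rate_PG
    if cfg.mode == "p_only":
        state.lambda_SG = simple_multiplicative_step(
            state.lambda_SG, state.conv_rate_SG, cfg.alpha_p, cfg.target_rate,
            bounds=cfg.bounds_SG, max_step=cfg.max_step)
        state.lambda_PG = simple_multiplicative_step(
            state.lambda_PG, state.conv_rate_PG, cfg.alpha_p, cfg.target_rate,
            bounds=cfg.bounds_PG, max_step=cfg.max_step)
    else:
        state.lambda_SG = _clamped_update(state.lambda_SG, err_sg,
                                          state.integral_error_SG, cfg.bounds_SG, cfg)
        state.lambda_PG = _clamped_update(state.lambda_PG, err_pg,
                                          state.integral_error_PG, cfg.bounds_PG, cfg)
    # integral accumulates on applied steps, after the update uses it
    state.integral_error_SG += err_sg
    state.integral_error_PG += err_pg
    state.epoch += 1
    return state


def observe_losses(state: ControllerState, loss_SG: float, loss_PG: float,
                   cfg: ControllerConfig | None = None) -> ControllerState:
    """Update both convergence-rate EWMAs from new loss observations."""
    cfg = cfg or ControllerConfig()
    if state.prev_loss_SG is not None and state.prev_loss_SG > 0:
        state.conv_rate_SG = update_convergence(state.conv_rate_SG, loss_SG,
                                                state.prev_loss_SG, cfg)
    if state.prev_loss_PG is not None and state.prev_loss_PG > 0:
        state.conv_rate_PG = update_convergence(state.conv_rate_PG, loss_PG,
                                                state.prev_loss_PG, cfg)
    state.prev_loss_SG = loss_SG
    state.prev_loss_PG = loss_PG
    return state


def constraint_trigger(metrics: dict, cfg: ControllerConfig | None = None,
                       epoch: int | None = None):
    """True (with the violated metric names) iff any plausibility metric is
    strictly below its threshold.  Intended to run only at epochs divisible
    by ``monitor_interval``."""
    cfg = cfg or ControllerConfig()
    if epoch is not None and cfg.monitor_interval > 0 and epoch % cfg.monitor_interval != 0:
        return False, []
    violated = [name for name, thr in cfg.thresholds.items()
                if metrics.get(name, 1.0) < thr]
    return bool(violated), violated


def sensitivity_probe(objective, lambda_current: float, delta: float = 0.20) -> dict:
    """Evaluate a deterministic scoring contract at lambda*(1-delta), lambda,
    lambda*(1+delta); returns the score table without mutating any state."""
    points = [lambda_current * (1 - delta), lambda_current, lambda_current * (1 + delta)]
    return {p: float(objective(p)) for p in points}


def simple_multiplicative_step(lam: float, conv_rate: float, alpha: float = 0.05,
                               target: float = 0.02, bounds: tuple | None = None,
                               max_step: float = 0.15) -> float:
    """Proportional-only alternative rule:
    lambda' = lambda * (1 + alpha * (conv_rate - target)), with the same
    step clipping and bound clamping as the PI rule."""
    proposed = lam * (1.0 + alpha * (conv_rate - target))
    delta = max(-max_step, min(max_step, proposed - lam))
    out = lam + delta
    if bounds is not None:
        out = max(bounds[0], min(bounds[1], out))
    return out
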