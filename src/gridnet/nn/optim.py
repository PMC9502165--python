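"""Adam optimizer with parameter groups and serializable state."""

from __future__ import annotations

import numpy as np

from .core import Param


class Adam:
    """Adam with per-group learning rates (conventional beta/eps defaults).

    ``groups`` is a list of ``{"params": [Param, ...], "lr": float}`` dicts,
    which lets the patch classifier f and the global corrector g be stepped
    at different rates within one optimizer.
    """

    def __init__(self, groups, betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8) -> None:
        if isinstance(groups, list) and groups and isinstance(groups[0], Param):
            raise TypeError("pass [{'params': [...], 'lr': lr}, ...] groups")
        self.groups = groups
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = [[np.zeros_like(p.value) for p in g["params"]] for g in groups]
        self.v = [[np.zeros_like(p.value) for p in g["params"]] for g in groups]

    def zero_grad(self) -> None:
        for g in self.groups:
            for p in g["params"]:
                p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for gi, g in enumerate(self.groups):
            lr = g["lr"]
            for pi, p in enumerate(g["params"]):
                m = self.m[gi][pi]
                v = self.v[gi][pi]
                m *= b1
                m += (1 - b1) * p.grad
                v *= b2
                v += (1 - b2) * p.grad ** 2
                p.value -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    # -- state round-trip --------------------------------------------------
    def state_dict(self) -> dict:
        return {
            "t": self.t,
            "m": [[a.copy() for a in grp] for grp in self.m],
            "v": [[a.copy() for a in grp] for grp in self.v],
            "lrs": [g["lr"] for g in self.groups],
        }

    def load_state_dict(self, state: dict) -> None:
        self.t = state["t"]
        for gi, grp in enumerate(state["m"]):
            for pi, arr in enumerate(grp):
                self.m[gi][pi][...] = arr
        for gi, grp in enumerate(state["v"]):
            for pi, arr in enumerate(grp):
                self.v[gi][pi][...] = arr
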