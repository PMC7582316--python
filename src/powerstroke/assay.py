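"""The dissociation-constant recovery protocol for the four MST assay
conditions.

Each condition's reported ADP affinity is used as the ground truth of the
synthetic generator (16-point 1:1 dilution from 10 mM, 2% Gaussian noise
on the normalized signal), and the Hill equation is fit back to every
replicate curve.  Because the generated signal is normalized fraction
bound, the fit uses the Hill equation proper (amplitude 1, baseline 0)
with the single-site coefficient n = 1; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hillfit import HillFit, fit_hill
from .synthetic import BindingCurveSpec, make_binding_curve

__all__ = ["CONDITIONS", "recover_kd", "KdRecovery"]

#: Assay conditions and their reported ADP dissociation constants
#: (ground truth for the synthetic curves): Mg2+ present/absent, with
#: and without 100 uM blebbistatin.  Values in uM.
CONDITIONS = {
    "+Mg": 37.5,
    "-Mg": 145.8,
    "+bleb+Mg": 21.2,
    "+bleb-Mg": 40.6,
}


@dataclass
class KdRecovery:
    condition: str
    kd_true: float
    kds: np.ndarray

    @property
    def median_kd(self) -> float:
        return float(np.median(self.kds))

    def fraction_within(self, half_width: float) -> float:
        lo, hi = self.kd_true - half_width, self.kd_true + half_width
        return float(np.mean((self.kds >= lo) & (self.kds <= hi)))


def recover_kd(
    kd_true: float,
    condition: str = "",
    n_replicates: int = 100,
    seed: int = 0,
    noise_sigma: float = 0.02,
) -> KdRecovery:
    """Generate ``n_replicates`` seeded synthetic titrations with
    ``kd_true`` and fit each with the normalized Hill equation (n = 1)."""
    rng = np.random.default_rng(seed)
    curve_seeds = rng.integers(0, 2**31 - 1, size=n_replicates)
    kds = []
    for s in curve_seeds:
        curve = make_binding_curve(
            BindingCurveSpec(
                kd_true=kd_true,
                noise_sigma=noise_sigma,
                seed=int(s),
                condition=condition,
            )
        )
        fit = fit_hill(curve, fix_n=1.0, fix_amplitude=1.0, fix_baseline=0.0)
        kds.append(fit.kd)
    return KdRecovery(condition=condition, kd_true=kd_true, kds=np.array(kds))
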