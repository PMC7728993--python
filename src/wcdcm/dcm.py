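"""Model/results front end for single-subject DCM inversion.

:class:`DCM` bundles a BOLD series, an input timeline and a model
specification; :meth:`DCM.fit` runs the variational-Laplace inversion and
returns :class:`DCMResults`, which carries the posterior means, their
posterior standard deviations, the free energy and fit diagnostics, and
renders a text ``summary()`` table. Forward simulation from chosen
parameters hangs off the model object.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .generative import BOLDSeries, InputTimeline, integrate
from .hemodynamics import HemodynamicParams
from .inversion import (InversionOptions, Posterior, PriorSpec,
                        default_priors, invert)
from .neuronal import ModelSpec, NeuronalParams

__all__ = ["DCM", "DCMResults"]


class DCM:
    """A dynamic causal model bound to one subject's data.

    Parameters
    ----------
    data : BOLDSeries
        Observed region-averaged BOLD, % signal change, sampled at TR.
    inputs : InputTimeline
        Experimental inputs on the microtime grid.
    spec : ModelSpec
        Network structure and neuronal variant.
    priors : PriorSpec, optional
        Defaults to the classical shrinkage priors for ``spec``.
    hemo : HemodynamicParams, optional
        Fixed balloon-model constants (per-region log-scalings on kappa
        and tau_h are estimated).
    """

    def __init__(self, data: BOLDSeries, inputs: InputTimeline,
                 spec: ModelSpec, priors: PriorSpec | None = None,
                 hemo: HemodynamicParams | None = None):
        self.data = data
        self.inputs = inputs
        self.spec = spec
        self.priors = priors if priors is not None else default_priors(spec)
        self.hemo = hemo if hemo is not None else HemodynamicParams()

    @classmethod
    def from_files(cls, bold_path, inputs_path, spec_path, **kwargs):
        """Build a model from a BOLD TSV, an inputs TSV and a spec JSON."""
        from .io import read_bold_tsv, read_inputs, read_spec_json
        return cls(read_bold_tsv(bold_path), read_inputs(inputs_path),
                   read_spec_json(spec_path), **kwargs)

    def fit(self, **options) -> "DCMResults":
        """Invert the model; keyword arguments override
        :class:`~wcdcm.inversion.InversionOptions` fields."""
        opts = InversionOptions(**options)
        post = invert(self.data, self.inputs, self.spec,
                      priors=self.priors, hemo=self.hemo, opts=opts)
        return DCMResults(self, post)

    def simulate(self, neuronal: NeuronalParams, hemo_scale=None,
                 duration: float | None = None) -> BOLDSeries:
        """Forward-simulate BOLD from given neuronal parameters."""
        if duration is None:
            duration = (self.data.n_samples - 1) * self.data.TR
        _, series = integrate(self.spec, neuronal, self.hemo, self.inputs,
                              duration, self.data.TR, hemo_scale=hemo_scale,
                              store_latents=False)
        return series


class DCMResults:
    """Posterior summary of one fitted DCM."""

    def __init__(self, model: DCM, posterior: Posterior):
        self.model = model
        self.posterior = posterior

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.posterior.mean, index=self.posterior.names)

    @property
    def bse(self) -> pd.Series:
        """Posterior standard deviations."""
        return pd.Series(self.posterior.sd(), index=self.posterior.names)

    def cov_params(self) -> pd.DataFrame:
        return pd.DataFrame(self.posterior.cov, index=self.posterior.names,
                            columns=self.posterior.names)

    @property
    def free_energy(self) -> float:
        return self.posterior.free_energy

    @property
    def explained_variance(self) -> float:
        return self.posterior.explained_variance

    @property
    def flatline(self) -> bool:
        return self.posterior.flatline

    @property
    def predicted(self) -> BOLDSeries:
        return self.posterior.predicted

    def presence_probabilities(self) -> pd.Series:
        """Per parameter: posterior probability that it is nonzero with a
        determinate sign, max(Pr>0, Pr<0)."""
        return pd.Series(self.posterior.sign_probability(),
                         index=self.posterior.names)

    def summary(self) -> str:
        spec = self.model.spec
        post = self.posterior
        lines = []
        lines.append("Dynamic Causal Model — VBL inversion")
        lines.append("=" * 64)
        lines.append(f"variant: {spec.variant:<22s} states: {spec.states}")
        lines.append(f"regions: {', '.join(spec.region_names)}")
        lines.append(f"samples: {self.model.data.n_samples:<5d}  "
                     f"TR: {self.model.data.TR} s")
        lines.append(f"free energy F:        {post.free_energy:12.3f} nats")
        lines.append(f"explained variance:   {post.explained_variance:12.2f} %")
        lines.append(f"iterations: {post.n_iterations}  "
                     f"converged: {post.converged}  flatline: {post.flatline}")
        lines.append("-" * 64)
        lines.append(f"{'parameter':<28s}{'mean':>10s}{'sd':>10s}"
                     f"{'P(sign)':>10s}")
        sd = post.sd()
        sp = post.sign_probability()
        for i, name in enumerate(post.names):
            lines.append(f"{name:<28s}{post.mean[i]:>10.3f}{sd[i]:>10.3f}"
                         f"{sp[i]:>10.3f}")
        lines.append("-" * 64)
        lam = np.exp(post.noise_mean)
        for r, rn in enumerate(spec.region_names):
            lines.append(f"noise sd [{rn}]: {1.0 / np.sqrt(lam[r]):.4f} "
                         f"(log-precision {post.noise_mean[r]:.2f})")
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (f"<DCMResults F={self.free_energy:.2f} "
                f"EV={self.explained_variance:.1f}%>")
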