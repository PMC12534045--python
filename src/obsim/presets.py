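"""Parameter presets for the standard simulation settings.

``default_params`` carries the published default values.  ``broad``
mirrors the broad-stimulus setting (larger dendritic fields and a slower
spontaneous rate), ``nonneurogenic`` the tuned non-neurogenic comparison
network, and ``scaled_down`` is a smaller network used by the test suite
for the stochastic, multi-seed checks.
"""

from __future__ import annotations

from .params import ModelParams

__all__ = ["default_params", "broad_params", "nonneurogenic_params",
           "scaled_down_params"]


def default_params(**overrides) -> ModelParams:
    """Defaults of the model (225 MCs, 900 initial GCs, full flags)."""
    return ModelParams().replace(**overrides) if overrides else ModelParams()


def broad_params(**overrides) -> ModelParams:
    """Broad Gaussian-stimulus setting: N_conn = 100, R0 = 0.005."""
    return ModelParams(n_conn=100, r0=0.005).replace(**overrides) \
        if overrides else ModelParams(n_conn=100, r0=0.005)


def nonneurogenic_params(**overrides) -> ModelParams:
    """Non-neurogenic comparison network, retuned so it learns and forgets
    at rates similar to the full model: uniform p = 0.15, R0 = 0.003."""
    base = ModelParams(
        neurogenesis=False, apoptosis=False, age_excitability=False,
        plasticity_mode="fast", p_young=0.15, r0=0.003,
        dendritic_elaboration=False)
    return base.replace(**overrides) if overrides else base


def scaled_down_params(**overrides) -> ModelParams:
    """Small network for fast multi-seed tests (not for headline results)."""
    base = ModelParams(n_mc=100, n_gc_init=400, n_add=4, n_shuffles=500)
    return base.replace(**overrides) if overrides else base
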