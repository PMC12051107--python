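import numpy as np
import pytest

from densigrad import (
    GaussianComponent,
    GradientFraction,
    GradientProfile,
    correct_baseline,
    fit_mixture,
    interpolate_ri,
    simulate_gradient,
    study_gradient_specs,
)


def profile_from_arrays(ri, conc, corrected=False) -> GradientProfile:
    """Build a profile with RI on every fraction (index 1 = highest RI)."""
    order = np.argsort(ri)[::-1]
    fracs = [
        GradientFraction(
            index=i + 1,
            refractive_index=float(ri[j]),
            raw_concentration=float(conc[j]),
            corrected_concentration=float(conc[j]) if corrected else None,
        )
        for i, j in enumerate(order)
    ]
    return GradientProfile(fractions=fracs)


def corrected_study_fit(scenario: str, k: int, seed: int, noise_cv: float = 0.02):
    """Simulate a study scenario, baseline-correct, and fit k components."""
    spec = study_gradient_specs(seed=seed, noise_cv=noise_cv)[scenario]
    corrected, _ = correct_baseline(interpolate_ri(simulate_gradient(spec)))
    return spec, fit_mixture(corrected, k=k)


@pytest.fixture
def bulk_component() -> GaussianComponent:
    """The quiescent bulk-DNA distribution (mean RI 1.3683, σ 0.00163)."""
    return GaussianComponent(mean=1.3683, sigma=0.00163, amplitude=10.0)
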