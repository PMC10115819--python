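"""Fit the extended pairwise maximum-entropy model and map its landscape.

Preprocesses the mock study into binary taxa + scaled chemicals with the
treatment/stage environment, fits (h, J, g_a, g_s) by stochastic
approximation, then enumerates stable community states across the
growth-stage gradient with chemicals clamped at their observed means.
"""

import numpy as np

from calfscape import (FitSettings, clamp_continuous, fit, generate_study,
                       landscape_over_gradient, preprocess_study)

study = generate_study(n_animals=12, seed=7)
components, env = preprocess_study(study.abundance, study.chemicals,
                                   study.metadata)
print(f"components: {components.n_components} "
      f"({components.n_m} genera + {components.n_c} chemicals), "
      f"{components.values.shape[0]} samples")

result = fit(components, env, seed=0,
             settings=FitSettings(n_iter=3000, n_chains=40, backend="sa"))
params = result.params
print(f"final moment mismatch (max abs): {result.trace[-1]:.3f}")

# clamp chemicals at their dataset means, keep the 12 most prevalent
# genera so the 2^N enumeration stays instant
kinds = components.component_kinds
chem_means = components.values_array[:, components.n_m:].mean(axis=0)
reduced, binary_idx = clamp_continuous(params, kinds, chem_means)
prevalence = components.values_array[:, :components.n_m].sum(axis=0)
top = np.argsort(prevalence)[::-1][:12]
sub = reduced.permuted(np.sort(top))

summaries, surface = landscape_over_gradient(
    sub, eps_a_values=(0.0, 1.0), eps_s_grid=[0.0, 0.53, 1.0],
    compute_basins=False)
for summ in summaries:
    print(f"eps_a={summ.env[0]:.0f} eps_s={summ.env[1]:.2f}: "
          f"{summ.n_minima} stable state(s), "
          f"lowest energy {min(e for _, e in summ.minima):.2f}")
print("-> few shallow minima that shift with treatment and age: no "
      "single typical stable community, the landscape read-out of a "
      "silently perturbed ecosystem.")
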