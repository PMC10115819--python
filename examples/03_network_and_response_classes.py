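"""Signed interaction network and treatment-response classification.

Estimates parameter p-values by repeated stochastic refits on a small
known community, keeps the significant couplings as a signed network,
and classifies the mock study's genera into the four (g_s, g_a)
response quadrants.
"""

import warnings

import numpy as np

from calfscape import (FitSettings, build_network, classify_response, fit,
                       generate_community, generate_study, preprocess_study,
                       significance)
from calfscape.synthetic import random_ground_truth

warnings.filterwarnings("ignore")

# --- network on a community with known couplings ---
model = random_ground_truth(6, seed=3, scale=1.2)
components, env = generate_community(model, 400, seed=4)
res = significance(components, env, n_reps=500, seed=5,
                   settings=FitSettings(backend="exact"))
net = build_network(res, alpha=0.05)
edges = net.to_edgelist()
print(f"significant couplings at alpha=0.05: {len(edges)} "
      f"({(edges['sign'] == 'positive').sum()} positive, "
      f"{(edges['sign'] == 'negative').sum()} negative)")
true_J = model.params.J
hits = sum(1 for _, r in edges.iterrows()
           if np.sign(true_J[int(r.source[1:]), int(r.target[1:])])
           == np.sign(r.J))
print(f"edge signs matching the generating couplings: {hits}/{len(edges)}")

# --- response classes on the mock study ---
study = generate_study(n_animals=12, seed=7)
comp, env = preprocess_study(study.abundance, study.chemicals,
                             study.metadata)
fit_res = fit(comp, env, seed=0,
              settings=FitSettings(n_iter=3000, n_chains=40, backend="sa"))
classes = classify_response(fit_res.params).set_index("component")
for genus in ("Methanobrevibacter", "Dorea"):
    row = classes.loc[genus]
    print(f"{genus}: g_a={row.g_a:+.2f} g_s={row.g_s:+.2f} "
          f"-> Group {row.group}")
print("-> the methanogen is promoted by treatment (g_a > 0), the "
      "butyrate producer suppressed (g_a < 0), matching the planted "
      "biology.")
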