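"""Latent factors and manifold dynamics of a synthetic session.

Reduces per-epoch alpha band-power features with PCA and t-SNE, then
measures what the embedding shows: task-cluster similarity, per-trial
trajectories with a closure metric, and the bifurcation view through
partial correlations with reference brain states.
"""

import warnings

import numpy as np

from eegmanifold import (
    SessionConfig,
    alpha_epochs,
    alpha_power_features,
    bifurcation_projection,
    cluster_similarity,
    dims_for_variance,
    generate_recording,
    pca,
    trajectories,
    tsne,
)

warnings.simplefilter("ignore")

cfg = SessionConfig(fs=200.0, stim_duration=4.0, rest_duration=2.0,
                    n_trials_per_class=8, response_fraction=1.0, seed=11)
rec, truth = generate_recording(cfg)
eps = alpha_epochs(rec, cap=cfg.stim_duration)
features = alpha_power_features(eps)
print(f"{eps.n_epochs} epochs x {eps.n_channels} channels of alpha band power")

# linear view: how many PCs explain 80% of the variance?
emb_pca = pca(features, n_components=2,
              labels=eps.labels, trial_ids=eps.trial_ids, time_ids=eps.time_ids)
evr = emb_pca.params["explained_variance_ratio"]
print(f"PCA: first two components explain {100 * evr[:2].sum():.1f}% of "
      f"variance; 80% needs {dims_for_variance(emb_pca, 0.8)} dimensions")

# nonlinear view
emb = tsne(features, perplexity=30, seed=0, n_iter=600,
           labels=eps.labels, trial_ids=eps.trial_ids, time_ids=eps.time_ids)
print(f"t-SNE: final KL divergence {emb.params['kl_final']:.3f}")

sim = cluster_similarity(emb)
within = np.mean(np.diag(sim.values.values))
between = np.mean(sim.values.values[~np.eye(5, dtype=bool)])
print(f"cluster similarity ({sim.convention}): within tasks {within:.3f}, "
      f"between tasks {between:.3f} - same-task states sit closer together")

traj = trajectories(emb)
closure = np.mean(list(traj.closure.values()))
print(f"mean trajectory closure (end-to-start distance / path length): "
      f"{closure:.3f} - small values indicate cyclic paths")

# bifurcation: project every state onto the digit-1 / digit-5 reference axes
ref_1 = features[eps.labels == 1].mean(axis=0)
ref_5 = features[eps.labels == 5].mean(axis=0)
coords = bifurcation_projection(features, ref_1, ref_5)
for lab in (1, 5):
    m = coords[eps.labels == lab].mean(axis=0)
    print(f"digit {lab} states: partial correlation with (ref1, ref5) = "
          f"({m[0]:.2f}, {m[1]:.2f})")
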