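"""Cross-validated evaluation on the standard synthetic benchmark.

Runs global fivefold cross-validation of the graph-regularized model against
a plain (unregularized) NMF baseline on the same folds, then the cold-start
protocol that removes a disease's entire association column.  AUC 0.5 is
chance level; the gap between the two models is the value added by the
similarity graphs.
"""

import dataclasses

import numpy as np

from mfmda import Hyperparams, PRESETS, generate, make_folds, run_cv_d, \
    run_fivefold

data = generate(dataclasses.replace(PRESETS["small"], seed=0))
ds = data.dataset
print(f"dataset: {ds.n_mirna} x {ds.n_disease}, {ds.n_edges} associations")

hyper = Hyperparams(seed=0)
plan = make_folds(ds, 5, seed=0)
rep = run_fivefold(ds, data.mesh_table, data.fs, hyper, fold_plan=plan)
rep_nmf = run_fivefold(ds, data.mesh_table, data.fs,
                       hyper.replace(lambda_m=0.0, lambda_d=0.0),
                       fold_plan=plan)
print(f"fivefold, graph-regularized: pooled AUC {rep.pooled_auc:.4f}, "
      f"pooled AUPR {rep.pooled_aupr:.4f}")
print(f"fivefold, plain NMF:         pooled AUC {rep_nmf.pooled_auc:.4f}, "
      f"pooled AUPR {rep_nmf.pooled_aupr:.4f}")

rng = np.random.default_rng(0)
subset = list(rng.choice(ds.disease_names, size=10, replace=False))
rep_cvd = run_cv_d(ds, data.mesh_table, data.fs, hyper,
                   disease_subset=subset)
print(f"cold start (CV_d), 10 diseases: mean per-disease AUC "
      f"{rep_cvd.pooled_auc:.4f}")
print("\nThe held-out positives rank far above chance; the regularized "
      "model beats the baseline because the similarity graphs carry the "
      "planted group structure, and cold-start prediction works because a "
      "new disease inherits its neighbours' latent profile.")
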