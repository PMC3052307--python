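"""Encode site windows and cross-validate the RBF-network classifier.

Uses the BLOSUM62 window encoding at the full 41-mer window and reports
pooled five-fold precision, sensitivity, specificity and accuracy.
"""

from ubilys import EncoderConfig, benchmark_params, build_feature_matrix, kfold, simulate

dataset = simulate(benchmark_params("distant"), seed=1)
config = EncoderConfig(n=20, blocks=("BLOSUM",))
X, labels, names, _ = build_feature_matrix(
    dataset.proteins, dataset.sites, dataset.profiles, config
)
print(f"feature matrix: {X.shape[0]} sites x {X.shape[1]} features")

cv = kfold(X, labels, k=5, seed=17, sigma=5.0, ridge=1e-8)
m = cv.pooled_metrics
print(f"pooled confusion counts: {cv.pooled}")
print(
    f"Pr={m.precision:.3f}  Sn={m.sensitivity:.3f}  "
    f"Sp={m.specificity:.3f}  Acc={m.accuracy:.3f}"
)
# Sensitivity is the fraction of true modification sites recovered;
# specificity the fraction of unmodified lysines correctly rejected.
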