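"""Compare feature encodings under shared cross-validation folds.

Trains one model per block combination — compositions, BLOSUM62 windows,
pooled PSSM, accessibility, secondary structure, and the composition+PSSM
combination — on the same synthetic proteome and fold assignment.
"""

from ubilys import EncoderConfig, benchmark_params, feature_comparison, simulate

dataset = simulate(benchmark_params("distant"), seed=1)
configs = {
    name: EncoderConfig(n=20, blocks=blocks)
    for name, blocks in [
        ("AAC", ("AAC",)),
        ("BLOSUM", ("BLOSUM",)),
        ("PSSM", ("PSSM400",)),
        ("ASA", ("ASA",)),
        ("SS", ("SS",)),
        ("AAC+PSSM", ("AAC", "PSSM400")),
    ]
}
table = feature_comparison(dataset, configs, k=5, seed=17)
print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
# Sequence-borne signal favours the position-resolved BLOSUM encoding;
# the structural channels reflect only the generator's ASA/SS biases.
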