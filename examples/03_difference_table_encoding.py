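"""Key-position selection and difference-table feature encoding.

Each window offset gets a chi-square after compression; offsets above the
mean are *key positions*.  A key position is encoded by the change in its
chi-square when one extra sample carrying a given residue is counted as
positive versus negative — positive scores mark residues enriched in true
sites.
"""

from succsite import GeneratorSpec, generate
from succsite.encoding import (
    build_difference_table,
    encode_features,
    select_key_positions,
)

frags = generate(GeneratorSpec(n_pos=300, n_neg=3000, planted_offsets=(-2, 1),
                               effect_size=0.5, seed=12))
model = select_key_positions(frags)
print("chi2 average: %.2f" % model.chi2_ave)
print("key offsets:", model.key_offsets, "window:", model.window)

table = build_difference_table(frags, model.key_offsets)
print("difference scores at offset -2 (top enriched residues):")
print(table.scores[-2].sort_values(ascending=False).head(3).round(3))

X = encode_features(frags[:5], table, model.window)
print("feature matrix:", X.shape, "->", list(X.columns[:4]), "...")
# Positional columns (P_*) are difference-table lookups; the remaining 230
# columns are residue and adjacent-pair frequencies inside the window.
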