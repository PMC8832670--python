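"""The ChiMIC dependence measure and Chi-MIC-share feature selection.

ChiMIC stays near 0 for independent variables (where the classical MIC
inflates), and reaches 1 for noiseless functional relations.  Chi-MIC-share
introduces features greedily, sharing each feature's relevance across its
redundancy with the already-introduced set, so exact duplicates add nothing.
"""

import numpy as np

from succsite import chimic_score, select_features

rng = np.random.default_rng(0)
x = rng.normal(size=100)
print("chimic(x, 2x+1)      = %.3f  (functional -> 1)" %
      chimic_score(x, 2 * x + 1).value)
print("chimic(x, noise)     = %.3f  (independent -> ~0)" %
      chimic_score(x, rng.normal(size=100)).value)
print("chimic(x, exp(x))    = %.3f  (monotone-transform invariant)" %
      chimic_score(x, np.exp(x)).value)

# selection: one relevant feature, an exact duplicate, three noise columns
n = 200
y = (rng.uniform(size=n) < 0.3).astype(float)
X = np.column_stack([y, y, rng.normal(size=(n, 3))])
result = select_features(X, y)
print("introduced features:", result.names)
print("share-score history:", [round(s, 3) for s in result.score_history])
# Only the relevant feature survives: the duplicate's redundancy halves both
# contributions (zero net gain) and the noise columns cannot raise the score.
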