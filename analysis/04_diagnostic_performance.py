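"""Diagnostic performance: ROC/Youden, logistic models, DeLong matrix.

Computes per-parameter ROC curves with Youden cutoffs, univariable odds
ratios, the forward-stepwise multivariable model, the combined
(selected parameter + node size) model, and all pairwise DeLong AUC
comparisons, writing the tables under results/study/.
"""

import argparse
from pathlib import Path

import pandas as pd

from dwinode.pipeline import table5_analogue
from dwinode.stats import delong_matrix, roc_table

parser = argparse.ArgumentParser()
parser.add_argument("--cohort", default="results/inputs/cohort.csv")
parser.add_argument("--out", default="results/study")
args = parser.parse_args()

cohort = pd.read_csv(args.cohort)
out = Path(args.out)
out.mkdir(parents=True, exist_ok=True)

t4 = roc_table(cohort)
t5 = table5_analogue(cohort)
dl = delong_matrix(cohort)
t4.to_csv(out / "table4_roc.csv")
t5["univariable"].to_csv(out / "table5_univariable.csv")
t5["multivariable"].to_csv(out / "table5_multivariable.csv")
dl.to_csv(out / "delong_matrix.csv")

print("ROC performance (metastatic = positive class):")
print(t4.round(3).to_string())
print(f"\nforward stepwise selected: {list(t5['selected'])}")
print("\nDeLong p, combined model vs single parameters:")
print(dl["combined"].drop("combined").round(4).to_string())
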