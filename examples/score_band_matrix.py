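"""Score CCGG methylation states from a small hand-written band matrix.

Each sample is digested twice: HpaII ("H" lane) and MspI ("M" lane).  A
band present in both lanes is an unmethylated site; M-only marks internal
(CG) methylation; H-only marks hemimethylated CHG; absent from both is
uninformative (full methylation or a missing fragment).
"""

import tempfile
from pathlib import Path

from msapop import (
    context_fractions,
    methylation_profile,
    read_band_matrix,
    score_matrix,
)

TSV = """\
band_id\tplantA_H\tplantA_M\tplantB_H\tplantB_M
site1\t1\t1\t1\t1
site2\t0\t1\t1\t1
site3\t1\t0\t0\t1
site4\t1\t0\t1\t0
site5\t0\t0\t1\t1
site6\t1\t1\t0\t1
"""

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "bands.tsv"
    path.write_text(TSV)
    bands = read_band_matrix(path)

calls = score_matrix(bands)
print("state codes (0=unmeth, 1=CG, 2=CHG, 3=uninformative):")
print(calls.states)

for sample in bands.sample_ids:
    p = methylation_profile(calls, sample)
    print(
        f"{sample}: {p.n_methylation_polymorphic}/{p.n_scored_sites} "
        f"lane-polymorphic sites -> methylation level "
        f"{100 * p.level:.1f}% ({p.n_chg} CHG, {p.n_cg} CG)"
    )

chg, cg = context_fractions(calls)
print(f"pooled context: {100 * chg:.0f}% CHG vs {100 * cg:.0f}% CG")
# The level is the fraction of scored CCGG sites whose two digests disagree
# within one plant; site5 in plantA is (0,0) and drops out of plantA's
# denominator because full methylation cannot be told from band absence.
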