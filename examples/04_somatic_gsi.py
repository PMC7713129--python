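"""Somatic consensus and germline-somatic interactions on a full bundle.

Runs every stage over a generated cohort: four-caller somatic consensus
(>=2 callers, hard filters a-e), then gene-level (two-hit in cis) and
pathway-level (hypergeometric ORA, p < 0.05) germline-somatic interactions.
"""

import tempfile
from pathlib import Path

from dgvar import SimulationConfig, generate_cohort, run_all

with tempfile.TemporaryDirectory() as tmp:
    bundle, truth = generate_cohort(SimulationConfig(seed=7, n_patients=24), Path(tmp) / "cohort")
    report = run_all(bundle.root, Path(tmp) / "run", seed=7)

    somatic = report.stages["somatic"]
    print(f"consensus somatic calls : {somatic['n_input']}")
    print(f"after hard filters      : {somatic['n_output']}")
    print(f"removed per criterion   : {somatic['removed']}")
    gsi = report.stages["gsi"]
    print(f"gene-level GSIs         : {gsi['n_gene_level']}")
    print(f"pathway-level GSIs      : {gsi['n_pathway_level']}")
    print(f"patients with pathway GSI: {gsi['patients_with_pathway_gsi']}")
    if "private_gsi_fraction" in gsi:
        print(f"tumors with private GSI : {gsi['private_gsi_fraction']:.0%}")
    # A gene-level GSI is a pDGV plus a somatic truncation or copy-number
    # loss in the same TSG; a pathway GSI is an enriched pathway harboring
    # both a germline and a (role-consistent) somatic hit. Private GSIs are
    # pathways altered in only one tumor of a multi-tumor patient.
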