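#!/usr/bin/env python
"""Sliding-window dN/dS scan (25-codon window, 5-codon step) on a simulated
coding-sequence pair with a positively selected run of codons, followed by
masking of the flagged windows — the screen used to ask whether localized
positive selection drives discordant tree signal."""
import json
from pathlib import Path

import numpy as np

from paralogon.phylo.alignment import Alignment
from paralogon.selection import mask_windows, sliding_dnds
from paralogon.simulate import simulate_codon_pair

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)
SEED = 7

rng = np.random.default_rng(SEED)
n_codons = 120
omega = np.full(n_codons, 0.1)       # background purifying selection
omega[50:70] = 4.0                   # positively selected run
seq_a, seq_b = simulate_codon_pair(n_codons, divergence=0.6, omega=omega,
                                   kappa=2.0, rng=rng)
aln = Alignment.from_sequences({"copy1": seq_a, "copy2": seq_b}, "dna",
                               from_cds=True)
scan = sliding_dnds(aln, ("copy1", "copy2"), window_aa=25, step_aa=5)
scan.to_tsv(OUT / "dnds_scan.tsv")

peak = scan.max_dn_window()
masked = mask_windows(aln, scan, ratio_threshold=1.0)
report = {
    "n_codons": n_codons,
    "elevated_run": [51, 70],
    "n_windows": len(scan.windows),
    "peak_window": [peak.start_codon, peak.end_codon],
    "peak_dn": peak.dN,
    "peak_ratio": peak.ratio,
    "columns_before_masking": int(aln.n_cols),
    "columns_after_masking": int(masked.n_cols),
}
(OUT / "selection_scan.json").write_text(json.dumps(report, indent=2) + "\n")

print(f"scan of {n_codons} codons in {len(scan.windows)} windows "
      f"written to {OUT/'dnds_scan.tsv'}")
print(f"peak dN window: codons {peak.start_codon}-{peak.end_codon} "
      f"(dN {peak.dN:.3f}, dN/dS "
      f"{'undefined' if peak.ratio is None else f'{peak.ratio:.2f}'}); "
      f"simulated elevated run: codons 51-70")
print(f"masking windows with dN/dS > 1 removes "
      f"{aln.n_cols - masked.n_cols} of {aln.n_cols} columns")
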