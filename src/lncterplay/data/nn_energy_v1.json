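{
  "version": "nn-energy-v1",
  "comment": "Pinned screening energy model, kcal/mol at 37 C. Stack keys are 'XY>ZW': pair XY (strand A base X with strand B base Y) followed 3'-ward on strand A by pair ZW. Watson-Crick stacks are Xia et al. 1998 nearest-neighbor values scaled to 70%; wobble (GU/UG)-containing stacks are set to a near-neutral -0.3 (0 for the weakest motif). The scaling plus the affine loop costs make the scorer deliberately conservative: at the package's transcript scale, chance hybrids essentially never reach the -20 screening cutoff while engineered full complements clear it by a wide margin. Energies are model-pinned screen scores, not thermodynamic predictions. Loop penalties are affine: bulge(l) = bulge_open + bulge_extend*(l-1); interior(la,lb) = interior_open + interior_extend*(la+lb-2).",
  "duplex_init": 4.09,
  "au_gu_end_penalty": 0.45,
  "bulge_open": 5.5,
  "bulge_extend": 0.9,
  "interior_open": 6.5,
  "interior_extend": 0.9,
  "max_loop": 15,
  "stack_energy": {
    "AU>AU": -0.651,
    "AU>UA": -0.77,
    "AU>CG": -1.568,
    "AU>GC": -1.456,
    "AU>GU": -0.3,
    "AU>UG": -0.3,
    "UA>AU": -0.931,
    "UA>UA": -0.651,
    "UA>CG": -1.645,
    "UA>GC": -1.477,
    "UA>GU": -0.3,
    "UA>UG": -0.3,
    "CG>AU": -1.477,
    "CG>UA": -1.456,
    "CG>CG": -2.282,
    "CG>GC": -1.652,
    "CG>GU": -0.3,
    "CG>UG": -0.3,
    "GC>AU": -1.645,
    "GC>UA": -1.568,
    "GC>CG": -2.394,
    "GC>GC": -2.282,
    "GC>GU": -0.3,
    "GC>UG": -0.3,
    "GU>AU": -0.3,
    "GU>UA": -0.3,
    "GU>CG": -0.3,
    "GU>GC": -0.3,
    "GU>GU": -0.3,
    "GU>UG": 0.0,
    "UG>AU": -0.3,
    "UG>UA": -0.3,
    "UG>CG": -0.3,
    "UG>GC": -0.3,
    "UG>GU": -0.3,
    "UG>UG": -0.3
  }
}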