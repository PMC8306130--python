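"""gsp-oncogene calling at GNAS codons 201 and 227.

Uses the package's synthetic reference coding sequence, introduces the
classic R201C activating substitution, and calls gsp status.
"""

from gnas_imprint import call_gsp, synthetic_reference_cds

reference = synthetic_reference_cds()

# wild type
print("wild type:", call_gsp("s_wt", reference, reference).status)

# R201C: codon 201 CGT (Arg) -> TGT (Cys)
start = 200 * 3
mutant = reference[:start] + "TGT" + reference[start + 3:]
call = call_gsp("s_mut", mutant, reference)
print(f"R201C mutant: {call.status} (codon {call.codon}, "
      f"{call.reference_residue} -> {call.observed_residue})")

# synonymous change at the hotspot stays negative
silent = reference[:start] + "CGC" + reference[start + 3:]
print("synonymous R201R:", call_gsp("s_syn", silent, reference).status)
print("-> only missense changes at Arg201 or Gln227 constitutively activate")
print("   Gsa; synonymous or off-hotspot variants are not gsp.")
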