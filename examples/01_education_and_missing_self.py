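"""NK-cell education and Bw4 missing-self from HLA/KIR genotypes.

Builds two donor/recipient pairs by hand, maps the HLA alleles to
KIR-ligand copy counts, assigns educated receptors and calls Bw4 loss.
"""

from nkgraft.immunogenetics import (HlaGenotype, KirGenotype,
                                    assign_education, call_bw4_loss,
                                    ligand_profile, load_epitope_table)

epitopes = load_epitope_table()

# Recipient 1: the common educating configuration Bw4+C1+C2, no A3/A11.
recipient = HlaGenotype("R1", alleles={
    "A": ("A*01:01", "A*02:01"),
    "B": ("B*44:02", "B*07:02"),   # one Bw4-motif allele
    "C": ("C*04:01", "C*07:01"),   # one C2, one C1
})
recipient_kir = KirGenotype("R1", kir3dl1=True, kir3dl2=True, kir2dl1=True,
                            kir2dl2=False, kir2dl3=True)

# Donor 1 carries no Bw4-motif allele at all.
donor = HlaGenotype("D1", alleles={
    "A": ("A*02:01", "A*03:01"),
    "B": ("B*07:02", "B*08:01"),
    "C": ("C*07:01", "C*07:02"),
})

r_profile = ligand_profile(recipient, epitopes)
d_profile = ligand_profile(donor, epitopes)
education = assign_education(r_profile, recipient_kir)
call = call_bw4_loss(r_profile, recipient_kir, d_profile, pair_id="R1/D1")

print(f"recipient ligands: Bw4 x{r_profile.bw4_copies}, "
      f"C1 x{r_profile.c1_copies}, C2 x{r_profile.c2_copies}, "
      f"A3/A11 {'present' if r_profile.a3a11_present else 'absent'}")
print(f"educated receptors: {sorted(education.educated_receptors)}")
print(f"donor Bw4 copies: {d_profile.bw4_copies}")
print(f"missing-self call: {call.category.value}")

# The recipient is educated through KIR3DL1 (Bw4), KIR2DL1 (C2) and
# KIR2DL2/L3 (C1) but not KIR3DL2 (no A3/A11); the donor encodes fewer Bw4
# copies than the recipient, so the pair is a Bw4-loss pair: the graft
# cannot restrain the recipient's Bw4-educated KIR3DL1+ NK cells.
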