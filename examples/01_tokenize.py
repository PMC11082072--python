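"""Tokenize one peptide two ways: single residues and residue pairs.

The two index sequences of the same peptide are what the two encoder
towers consume; they form the positive pair for contrastive learning.
"""

from pepclr import build_vocabulary, tokenize

v_single = build_vocabulary("single")
v_pair = build_vocabulary("pair")

peptide = "KWKLFKKIEK"
single = tokenize(peptide, v_single)
pair = tokenize(peptide, v_pair)

print(f"peptide: {peptide} (length {len(peptide)})")
print(f"single-residue vocabulary: {len(v_single)} tokens "
      f"(indices 0..{max(v_single.token_to_index.values())})")
print(f"residue-pair vocabulary:  {len(v_pair)} tokens "
      f"(indices 0..{max(v_pair.token_to_index.values())})")
print(f"single-mode indices ({len(single)} tokens): {single}")
print(f"pair-mode indices   ({len(pair)} tokens): {pair}")
print("Both lists start with the start token (index 1); pair mode reads "
      "non-overlapping residue pairs, so it is roughly half as long.")
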