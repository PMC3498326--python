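# The chemical typing vocabulary: 24 fragment classes (ligand-side atom
# triples, typed by the Main-atom) and 13 contact-atom (target) classes
# (protein atoms typed by element, residue and chain part). The matcher rules
# implementing these descriptions live in contactprefs.fragments; this file is
# the packaged, human-readable vocabulary mirror.
fragment_classes:
  f2:  {main: O, description: Hydroxyl oxygen bonded to a non-planar aliphatic structure}
  f3:  {main: O, description: Hydroxyl oxygen bonded to an aromatic structure}
  f5:  {main: O, description: Carbonyl oxygen (excluding those belonging to f9 and f10)}
  f6:  {main: O, description: Oxygen of a carboxyl group}
  f7:  {main: O, description: Carbamoyl oxygen}
  f8:  {main: O, description: Oxygen bonded to a phosphate group}
  f9:  {main: O, description: Amide group oxygen bonded to a non-aromatic structure}
  f10: {main: O, description: Amide group oxygen bonded to an aromatic structure}
  f11: {main: C, description: Secondary carbon in an aromatic structure}
  f12: {main: C, description: Secondary carbon in a non-aromatic structure}
  f13: {main: C, description: Primary carbon (with one hydrogen)}
  f17: {main: F, description: Fluorine bonded to an aromatic structure}
  f18: {main: F, description: Fluorine bonded to a non-aromatic structure}
  f20: {main: CL, description: Chlorine bonded to an aromatic structure}
  f21: {main: CL, description: Chlorine bonded to a non-aromatic structure}
  f22: {main: N, description: Nitrogen in an aromatic structure (without a substituent)}
  f23: {main: N, description: Nitrogen in a non-aromatic planar ring structure (without a substituent)}
  f26: {main: N, description: Amino (primary) nitrogen singly bonded to a non-aromatic structure}
  f27: {main: N, description: Amino (primary) nitrogen bonded to an aromatic structure}
  f29: {main: N, description: Amino (primary) nitrogen singly bonded to a planar structure}
  f34: {main: BR, description: Bromine bonded to an aromatic structure}
  f35: {main: BR, description: Bromine bonded to an aliphatic structure}
  f36: {main: I, description: Iodine bonded to an aromatic structure}
  f37: {main: I, description: Iodine bonded to an aliphatic structure}
target_classes:
  C3:  {element: C, chain_part: side, description: Carbon of a methyl group}
  C4:  {element: C, chain_part: main, description: Alpha carbon}
  C5:  {element: C, chain_part: side, description: Carbon in an aromatic structure}
  C6:  {element: S, chain_part: side, description: Sulfur of a thioether group}
  C7:  {element: S, chain_part: side, description: Sulfur of a thiol group}
  C8:  {element: N, chain_part: side, description: Nitrogen of an amide group}
  C9:  {element: N, chain_part: side, description: Nitrogen of indole, imidazole and guanido groups}
  C10: {element: N, chain_part: side, description: Nitrogen of an amino group}
  C11: {element: O, chain_part: side, description: Oxygen of a carboxamide group}
  C12: {element: O, chain_part: side, description: Oxygen of a carboxyl group}
  C13: {element: O, chain_part: side, description: Oxygen of a hydroxyl group}
  C14: {element: O, chain_part: main, description: Main chain carbonyl oxygen}
  C15: {element: N, chain_part: main, description: Main chain amide nitrogen}
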