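# Implausible single-element adducts used to generate decoy ions.
# One adduct per line; lines starting with '#' are ignored.
# User-overridable: pass a custom universe to sample_decoy_adducts /
# build_candidates to replace this list.
+He
+Li
+Be
+B
+F
+Ne
+Mg
+Al
+Si
+Ar
+Ca
+Sc
+Ti
+V
+Cr
+Mn
+Fe
+Co
+Ni
+Cu
+Zn
+Ga
+Ge
+As
+Se
+Kr
+Rb
+Sr
+Y
+Zr
+Nb
+Mo
+Ru
+Rh
+Pd
+Ag
+Cd
+In
+Sn
+Sb
+Te
+Xe
+Cs
+Ba
+La
+Ce
+Pr
+Nd
+Sm
+Eu
+Gd
+Tb
+Dy
+Ho
+Er
+Tm
+Yb
+Lu
+Hf
+Ta
+W
+Re
+Os
+Ir
+Pt
+Au
+Hg
+Tl
+Pb
+Bi
+Th
+U
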