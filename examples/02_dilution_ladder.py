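"""The FAC dilution ladder.

Builds the 11-step concentration table used for ex vivo treatment:
5-FU : doxorubicin : 4-HC at the clinical molar ratio 46:1:22, stepping
down /2, /2, /2.5 (one decade every three dilutions), with dilution 11 as
the untreated control.
"""

from slicequant import build_dilution_table

series = build_dilution_table()
print(series.table.to_string(index=False))
print()
for d in (1, 4, 7):
    r = series.concentration(d, "dox") / series.concentration(d + 3, "dox")
    print(f"c(dilution {d}) / c(dilution {d + 3}) = {r:.1f}  (decade spacing)")
print()
print("Dilution 1 is the strongest exposure, dilution 10 the weakest; a tumor")
print("responding at a larger dilution index is the more chemosensitive one.")
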