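"""The two wet-lab summary formulas on toy numbers.

2**(-ddCt) relative expression (reference gene + control condition) and
background-corrected relative viability from plate-reader optical density.
"""

import cochnet as cn

# target gene 1 cycle later than in control, reference unchanged -> halved
fold = cn.delta_delta_ct(ct_target_trt=25, ct_ref_trt=20,
                         ct_target_ctl=24, ct_ref_ctl=20)
print(f"ddCt = +1  -> fold change {fold:.2f} (expression halved)")

fold = cn.delta_delta_ct(23, 20, 24, 20)
print(f"ddCt = -1  -> fold change {fold:.2f} (expression doubled)")

for od_exp, label in ((1.20, "untreated"), (0.65, "mid dose"),
                      (0.21, "high dose")):
    pct, flag = cn.relative_viability(od_exp, od_pos=0.10, od_neg=1.20)
    print(f"OD {od_exp:.2f} ({label:9s}) -> viability {pct:5.1f}%"
          + ("  [outside 0-100, flagged]" if flag else ""))
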