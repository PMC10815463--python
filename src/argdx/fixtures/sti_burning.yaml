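# Diagnostic table for the presenting complaint "burning and/or itching" in
# the sexually-transmitted-infection group.  Progressive refinement with
# inter-menstrual / post-coital bleeding and cauliflower-shaped lumps leads
# to anogenital warts (AW).  The table has an HIV column; HP (hepatitis)
# belongs to the group but has no column, so it sits in the registry only.
registry:
- {code: BV, label: bacterial vaginosis, group: sexually_transmitted_infections}
- {code: TM, label: trichomoniasis, group: sexually_transmitted_infections}
- {code: VC, label: vulva candidiasis, group: sexually_transmitted_infections}
- {code: SP, label: syphilis, group: sexually_transmitted_infections}
- {code: NG, label: Neisseria gonorrhoeae, group: sexually_transmitted_infections}
- {code: CM, label: chlamydia, group: sexually_transmitted_infections}
- {code: HSV, label: herpes simplex virus II, group: sexually_transmitted_infections}
- {code: AW, label: anogenital warts, group: sexually_transmitted_infections}
- {code: HIV, label: human immunodeficiency virus, group: sexually_transmitted_infections}
- {code: HP, label: hepatitis, group: sexually_transmitted_infections}
tables:
- table_id: sti_burning
  presenting: burning +/ itching
  diseases: [BV, TM, VC, SP, NG, CM, HSV, AW, HIV]
  rows:
  - row_id: r1
    parent: null
    adds: [burning +/ itching]
    select: [BV, TM, VC, NG, CM, HSV, AW]
  - row_id: r2
    parent: r1
    adds: [intermenstrual_bleeding +/ postcoital_bleeding]
    select: [VC, NG, CM, AW]
  - row_id: r3
    parent: r2
    adds: ['lumps(small_cauliflower) +/ image(2, condyloma)']
    select: [AW]
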