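# Diagnostic table for the presenting complaint "vaginal discharge" in the
# sexually-transmitted-infection group, with the row selections as printed
# (row 1 supports BV, TM, VC, NG and CM).  A variant following the running
# prose, which additionally keeps AW at the root, ships as
# sti_discharge_prose.yaml.  The registry is restricted to the table's eight
# disease columns, so D = 8 for accuracy computations on this fixture.
registry:
- {code: BV, label: bacterial vaginosis, group: sexually_transmitted_infections}
- {code: TM, label: trichomoniasis, group: sexually_transmitted_infections}
- {code: VC, label: vulva candidiasis, group: sexually_transmitted_infections}
- {code: SP, label: syphilis, group: sexually_transmitted_infections}
- {code: NG, label: Neisseria gonorrhoeae, group: sexually_transmitted_infections}
- {code: CM, label: chlamydia, group: sexually_transmitted_infections}
- {code: HSV, label: herpes simplex virus II, group: sexually_transmitted_infections}
- {code: AW, label: anogenital warts, group: sexually_transmitted_infections}
tables:
- table_id: sti_discharge
  presenting: vaginal_discharge
  diseases: [BV, TM, VC, SP, NG, CM, HSV, AW]
  rows:
  - row_id: r1
    parent: null
    adds: [vaginal_discharge]
    select: [BV, TM, VC, NG, CM]
  - row_id: r2
    parent: r1
    adds: ['quantity(vd, profuse)', 'texture(vd, thin)', 'colour(vd, green)']
    select: [BV, TM, NG]
  - row_id: r3
    parent: r2
    adds: ['texture(vd, frothy)']
    select: [BV, TM]
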