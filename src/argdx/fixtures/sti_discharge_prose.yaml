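# Prose variant of sti_discharge.yaml: the root scenario supports all eight
# diseases of the group except SP and HSV, i.e. AW stays in the root row's
# selection.  Deeper rows are identical to the printed table.
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
    select: [BV, TM, VC, NG, CM, AW]
  - row_id: r2
    parent: r1
    adds: ['quantity(vd, profuse)', 'texture(vd, thin)', 'colour(vd, green)']
    select: [BV, TM, NG]
  - row_id: r3
    parent: r2
    adds: ['texture(vd, frothy)']
    select: [BV, TM]
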