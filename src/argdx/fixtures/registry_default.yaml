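# Default disease registry: the named diseases of the seven gynaecological
# presentation groups (bleeding, endocrinology, cancer, pelvic pain,
# urogynaecology, sexually transmitted infections, vulva pathology).
# A valid knowledge base with no tables; D = |registry| = 45.  Vulva cancer
# is named under two groups in the source material; codes must be unique, so
# it is registered once, under vulva_pathology.
registry:
- {code: CP, label: colonic polyps, group: bleeding}
- {code: EP, label: endometrial polyps, group: bleeding}
- {code: MC, label: miscarriage, group: bleeding}
- {code: PA, label: placenta abruption, group: bleeding}
- {code: PPV, label: placenta previa, group: bleeding}
- {code: CE, label: cervical erosion, group: bleeding}
- {code: CUS, label: Cushing's syndrome, group: endocrinology}
- {code: AT, label: adrenal tumour, group: endocrinology}
- {code: DP, label: delayed puberty, group: endocrinology}
- {code: MRKS, label: Mayer-Rokitansky-Kuster syndrome, group: endocrinology}
- {code: CXCA, label: cervical cancer, group: cancer}
- {code: EMCA, label: endometrial cancer, group: cancer}
- {code: OVCA, label: ovarian cancer, group: cancer}
- {code: VACA, label: vaginal cancer, group: cancer}
- {code: APX, label: appendicitis, group: pelvic_pain}
- {code: ECT, label: ectopic pregnancy, group: pelvic_pain}
- {code: ADH, label: adhesions, group: pelvic_pain}
- {code: DIV, label: diverticulitis, group: pelvic_pain}
- {code: OCR, label: ovarian cyst rupture, group: pelvic_pain}
- {code: OT, label: ovarian torsion, group: pelvic_pain}
- {code: RCL, label: ruptured corpus luteum, group: pelvic_pain}
- {code: ADM, label: adenomyosis, group: pelvic_pain}
- {code: MAO, label: mesenteric artery occlusion, group: pelvic_pain}
- {code: EMS, label: endometriosis, group: pelvic_pain}
- {code: ROF, label: ruptured ovarian follicles, group: pelvic_pain}
- {code: FIB, label: fibroids, group: pelvic_pain}
- {code: FTT, label: fallopian tube torsion, group: pelvic_pain}
- {code: LEI, label: leiomyoma, group: pelvic_pain}
- {code: ADT, label: adnexal tumour, group: pelvic_pain}
- {code: BI, label: bowel infection, group: pelvic_pain}
- {code: BO, label: bowel obstruction, group: pelvic_pain}
- {code: NEP, label: nephrolithiasis, group: urogynaecology}
- {code: PYE, label: pyelonephritis, group: urogynaecology}
- {code: AW, label: anogenital warts, group: sexually_transmitted_infections}
- {code: BV, label: bacterial vaginosis, group: sexually_transmitted_infections}
- {code: HP, label: hepatitis, group: sexually_transmitted_infections}
- {code: CM, label: chlamydia, group: sexually_transmitted_infections}
- {code: TM, label: trichomoniasis, group: sexually_transmitted_infections}
- {code: VC, label: vulva candidiasis, group: sexually_transmitted_infections}
- {code: NG, label: Neisseria gonorrhoeae, group: sexually_transmitted_infections}
- {code: SP, label: syphilis, group: sexually_transmitted_infections}
- {code: HSV, label: herpes simplex virus II, group: sexually_transmitted_infections}
- {code: HIV, label: human immunodeficiency virus, group: sexually_transmitted_infections}
- {code: VIN, label: vulva intraepithelial neoplasia, group: vulva_pathology}
- {code: VUCA, label: vulva cancer, group: vulva_pathology}
tables: []
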