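# Narrative templates for the synthetic EHR corpus.
# Every negative-findings variant negates every complication lexicon term
# (the tear slot is swapped for affirmative language in planted
# complication cases); the generator self-test verifies that flagging a
# generated corpus recovers the planted truth exactly.
op_report:
  opening:
    - "the patient was brought to the operating room and the {eye} eye was prepped and draped in the usual sterile fashion."
    - "after informed consent was obtained, the {eye} eye was prepped and draped in standard fashion."
  biopsy:
    needle:
      - "at the start of the case, a 30-gauge needle on a 1-ml syringe was inserted through the peripheral cornea over the iris plane and 50 to 100 microliters of aqueous humor were aspirated."
    cannula:
      - "a paracentesis was made with a 15-degree blade, an angled 30-gauge blunt cannula on a 1-ml syringe was introduced into the anterior chamber, and 50 to 100 microliters of aqueous humor were aspirated."
  negative_findings:
    - "there was no lens touch and no iris touch. there was no cornea touch. no bleeding and no hemorrhage were seen and there was no hyphema. {tear_sentence} the wound was watertight without leak. the chamber did not shallow. no problems from patient movement occurred. no suprachoroidal hemorrhage was seen."
    - "no lens touch and no iris touch occurred. no cornea touch was noted. there was no bleeding, no hemorrhage, and no hyphema. {tear_sentence} no leak was seen and the chamber did not shallow. there were no problems with patient movement. no suprachoroidal hemorrhage occurred."
    - "no lens touch or iris touch was seen. there was no cornea touch. the anterior chamber remained deep and did not shallow; there was no bleeding, no hemorrhage, and no hyphema. {tear_sentence} the wound was watertight without leak. no patient movement problems occurred. no suprachoroidal hemorrhage was seen."
  tear_negative:
    - "no tear of descemet membrane was seen."
    - "there was no descemet membrane tear."
  tear_affirmative:
    - "on aspiration there was mild shallowing of the anterior chamber and a small descemet membrane tear was noted adjacent to the paracentesis. the tear remained localized and small without extension."
  body_anesthesia_note:
    - "anesthesia was provided by the anesthesia service; {label} anesthesia was administered."
  closing:
    - "the patient tolerated the procedure well and was transferred to the recovery area in stable condition."
anesthesia_section:
  topical:
    - "topical anesthesia with intracameral preservative-free lidocaine."
    - "topical tetracaine drops with intracameral lidocaine."
  peribulbar:
    - "peribulbar block with 2% lidocaine and 0.75% bupivacaine."
  subtenon:
    - "subtenon injection of 2% lidocaine."
  retrobulbar:
    - "retrobulbar block with lidocaine and bupivacaine."
  general:
    - "general anesthesia with endotracheal intubation."
    - "general endotracheal anesthesia."
  misuse:
    - "transient general anesthesia; intravenous sedation was administered and {local} anesthesia was given."
    - "transient general anesthesia with intravenous sedation and {local} anesthesia."
  no_hit:
    - "monitored anesthesia care."
    - ""
clinical_note:
  routine:
    - "postoperative day {day} examination of the {eye} eye. the eye is quiet and the cornea is clear. no signs of endophthalmitis. the wound is secure and vision is stable."
    - "seen in clinic on postoperative day {day}. the anterior chamber is deep and quiet. no endophthalmitis. intraocular pressure is within normal limits."
  preexisting_endophthalmitis:
    - "the patient presented with acute endophthalmitis of the {eye} eye. an intravitreal antibiotic injection was administered and the patient will be followed closely."
adversarial:
  - "the tear film was stable throughout."
  - "the wound was leak-free at the end of the case."
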