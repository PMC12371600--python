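# Default theme hierarchy: five root themes with subtheme branches, plus the
# seven broad post categories kept as a parallel label system.  Every node
# carries a keyword seed list used by the reference (auditable) top-down
# classifier and an actionability flag; emotional-support content is the
# canonical nonactionable case.
roots:
  disease burden:
    seeds: ["daily struggle", "taking a toll", exhausting, burden]
    actionable: true
  treatment decision:
    seeds: ["weighing the options", "decide between", "hard decision", "choose a treatment"]
    actionable: true
  unmet needs:
    seeds: ["no one could tell us", "lack of", "wish there was", "unmet need"]
    actionable: true
  life milestones:
    seeds: [wedding, graduation, anniversary, grandchild, birthday, milestone]
    actionable: false
  logistic burden:
    seeds: ["long drive", parking, paperwork, scheduling, "out of pocket", copay]
    actionable: true
subthemes:
  blood counts:
    roots: [disease burden]
    seeds: ["blood counts", hemoglobin, platelets, neutrophils, "cbc results"]
    actionable: true
  quality of life:
    roots: [disease burden, unmet needs]
    seeds: ["quality of life", "everyday activities", "energy levels", independence]
    actionable: true
  treatment options:
    roots: [treatment decision]
    seeds: ["treatment options", "which treatment", "best option", "other treatments"]
    actionable: true
  disease progression:
    roots: [disease burden]
    seeds: [progression, "getting worse", advancing, "blasts rising"]
    actionable: true
  diagnostic process:
    roots: [logistic burden, unmet needs]
    seeds: ["waiting for results", biopsy, "second opinion", "diagnostic process"]
    actionable: true
  treatment modalities:
    roots: [treatment decision]
    seeds: [chemotherapy, regimen, injections, "treatment cycles", "side effects of treatment"]
    actionable: true
  hematological management:
    roots: [disease burden]
    seeds: ["iron overload", neutropenia, "growth factors", "transfusion schedule"]
    actionable: true
  navigating the health care system:
    roots: [logistic burden]
    seeds: [insurance, referral, "health care system", specialist, "switching doctors"]
    actionable: true
  knowledge constraints:
    roots: [unmet needs]
    seeds: ["hard to find information", "what does it mean", "nobody explained", "so little information"]
    actionable: true
  ongoing research:
    roots: [unmet needs]
    seeds: ["ongoing research", "new studies", "latest findings", "research news"]
    actionable: true
  health complications:
    roots: [disease burden]
    seeds: [infection, pneumonia, complications, hospitalized]
    actionable: true
  transplant experience:
    roots: [treatment decision, life milestones]
    seeds: [donor, engraftment, "transplant experience", conditioning]
    actionable: true
  disease understanding:
    roots: [unmet needs]
    seeds: ["understanding the disease", "make sense of the diagnosis", "what mds means"]
    actionable: true
  treatment information:
    roots: [unmet needs, treatment decision]
    seeds: ["information about treatment", "treatment information", "details on the therapy"]
    actionable: true
  emotional support:
    roots: [unmet needs]
    seeds: ["thinking of you", hugs, "stay strong", "here for you", "sending love"]
    actionable: false
categories:
  clinical: [diagnosis, prognosis, monitoring, "blood counts", blasts, biopsy, cytogenetics]
  diet and lifestyle: [diet, nutrition, exercise, appetite, lifestyle]
  education and logistics: [information, resources, insurance, appointment, travel, logistics]
  emotional: [support, hugs, "thinking of you", encouragement, "stay strong"]
  physical: [fatigue, tired, symptoms, "side effects", pain, nausea]
  transplants: [transplant, donor, engraftment, conditioning, graft]
  treatments: [treatment, chemotherapy, azacitidine, transfusion, regimen, cycles]
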