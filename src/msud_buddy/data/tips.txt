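General care tips for caregivers of infants with MSUD
======================================================
These tips are generic reminders, not medical advice.  Replace or extend
this file with guidance reviewed by your metabolic care team.

* Keep every scheduled appointment with the pediatrician and metabolic
  dietitian; plasma amino-acid levels in the first six months should be
  re-checked every 2-4 weeks and the feeding plan re-derived after each
  result.
* Never change formula brands, scoop sizes, or feed counts without
  consulting the metabolic dietitian.
* Measure powder with the standard scoop supplied with the plan (5 g level
  scoops by default) - heaped or packed scoops deliver more amino acids
  than the plan allows.
* During illness, vomiting, or poor feeding, contact the metabolic team
  immediately: catabolic stress raises plasma leucine even without intake.
* Watch for early warning signs of decompensation - poor feeding,
  irritability, unusual sleepiness, a maple-syrup odour of the urine or
  earwax - and seek urgent care if they appear.
* Keep an emergency letter from your metabolic centre with you when
  travelling.
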