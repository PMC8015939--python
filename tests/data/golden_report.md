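# Pharmacogenomic Report

Generated on: 2021-03-01  
Knowledge base: fixture-1.0 (last updated 2021-02-01)

## Labels

- specimen: S-001

## Genetic Results

| Gene | Genotype | Diplotype | Inferred phenotype | Converted phenotype | Basis | Note |
| --- | --- | --- | --- | --- | --- | --- |
| CYP2B6 | *1/*6 | *1/*6 | intermediate metabolizer | — | no_trigger |  |
| CYP2C19 | *1/*2 | *1/*2 | intermediate metabolizer | poor metabolizer | moderate_inhibitor |  |
| CYP2C9 | *1/*1 | *1/*1 | normal metabolizer | — | no_trigger |  |
| CYP2D6 | *2/*1 | *1/*2 | normal metabolizer | poor metabolizer | strong_inhibitor | array panel |
| CYP3A5 | *3/*3 | *3/*3 | poor metabolizer | — | no_trigger |  |
| HLA-A | *31:01 negative | *31:01 negative | *31:01 negative | — | not_applicable |  |
| HLA-B | 57:01 pos | *57:01 positive | *57:01 positive | — | not_applicable |  |
| NUDT15 | *1/*1 | *1/*1 | normal metabolizer | — | not_applicable |  |
| SLCO1B1 | *1/*5 | *1/*5 | decreased function | — | not_applicable |  |
| TPMT | *1/*3A | *1/*3A | intermediate metabolizer | — | not_applicable |  |
| VKORC1 | G/A | A/G | increased warfarin sensitivity | — | not_applicable |  |

## Current Medications

Entered: paroxetine, omeprazole

| Gene | Substrates | Weak inhibitors | Moderate inhibitors | Strong inhibitors | Inducers |
| --- | --- | --- | --- | --- | --- |
| CYP2B6 | — | — | — | — | — |
| CYP2C19 | omeprazole | — | omeprazole | — | — |
| CYP2C9 | — | — | — | — | — |
| CYP2D6 | — | — | — | paroxetine | — |
| CYP3A5 | — | — | — | — | — |

## Future Medications

| Drug | Class | Gene(s) | Phenotype(s) | Recommendation | Strength | Source | Actionable |
| --- | --- | --- | --- | --- | --- | --- | --- |
| abacavir | antiretroviral | HLA-B | HLA-B: *57:01 positive | Placeholder fixture guidance (CPIC): abacavir with HLA-B *57:01 positive. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| acenocoumarol | anticoagulant | VKORC1 | VKORC1: increased warfarin sensitivity | Placeholder fixture guidance (CPIC): acenocoumarol with VKORC1 increased warfarin sensitivity. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| allopurinol | antigout | HLA-B | HLA-B: *57:01 positive | No recommendation on record for HLA-B *57:01 positive. | none | — | no |
| amiodarone | other | CYP2D6 | CYP2D6: poor metabolizer | Placeholder fixture guidance (CPIC): amiodarone with CYP2D6 poor metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| amitriptyline | TCA | CYP2C19, CYP2D6 | CYP2C19: poor metabolizer; CYP2D6: poor metabolizer | Placeholder fixture guidance (CPIC): amitriptyline with CYP2C19 poor metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| amphetamine | stimulant | CYP2D6 | CYP2D6: poor metabolizer | Placeholder fixture guidance (CPIC): amphetamine with CYP2D6 poor metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| aripiprazole | antipsychotic | CYP2D6 | CYP2D6: poor metabolizer | Placeholder fixture guidance (CPIC): aripiprazole with CYP2D6 poor metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| aspirin | antiplatelet | CYP2C9 | CYP2C9: normal metabolizer | Placeholder fixture guidance (CPIC): aspirin with CYP2C9 normal metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | optional | CPIC | no |
| atenolol | beta-blocker | CYP2D6 | CYP2D6: poor metabolizer | Placeholder fixture guidance (CPIC): atenolol with CYP2D6 poor metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| atomoxetine | other | CYP2D6 | CYP2D6: poor metabolizer | Placeholder fixture guidance (CPIC): atomoxetine with CYP2D6 poor metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| atorvastatin | statin | SLCO1B1 | SLCO1B1: decreased function | Placeholder fixture guidance (CPIC): atorvastatin with SLCO1B1 decreased function. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| azathioprine | thiopurine | NUDT15, TPMT | NUDT15: normal metabolizer; TPMT: intermediate metabolizer | Placeholder fixture guidance (CPIC): azathioprine with NUDT15 normal metabolizer; TPMT intermediate metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| bisoprolol | beta-blocker | CYP2D6 | CYP2D6: poor metabolizer | Placeholder fixture guidance (CPIC): bisoprolol with CYP2D6 poor metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| brexpiprazole | antipsychotic | CYP2D6 | CYP2D6: poor metabolizer | Placeholder fixture guidance (CPIC): brexpiprazole with CYP2D6 poor metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| carbamazepine | antiepileptic | HLA-A, HLA-B | HLA-A: *31:01 negative; HLA-B: *57:01 positive | Placeholder fixture guidance (CPIC): carbamazepine with HLA-A *31:01 negative. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | optional | CPIC | no |
| cavedilol | beta-blocker | CYP2D6 | CYP2D6: poor metabolizer | Placeholder fixture guidance (CPIC): cavedilol with CYP2D6 poor metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| celecoxib | NSAID | CYP2C9 | CYP2C9: normal metabolizer | Placeholder fixture guidance (CPIC): celecoxib with CYP2C9 normal metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | optional | CPIC | no |
| citalopram | SSRI | CYP2C19 | CYP2C19: poor metabolizer | Placeholder fixture guidance (CPIC): citalopram with CYP2C19 poor metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| clobazam | antiepileptic | CYP2C19 | CYP2C19: poor metabolizer | Placeholder fixture guidance (CPIC): clobazam with CYP2C19 poor metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| clomipramine | TCA | CYP2C19, CYP2D6 | CYP2C19: poor metabolizer; CYP2D6: poor metabolizer | Placeholder fixture guidance (CPIC): clomipramine with CYP2C19 poor metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| clonidine | other | CYP2D6 | CYP2D6: poor metabolizer | Placeholder fixture guidance (CPIC): clonidine with CYP2D6 poor metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| clopidogrel | antiplatelet | CYP2C19 | CYP2C19: poor metabolizer | Placeholder fixture guidance (CPIC): clopidogrel with CYP2C19 poor metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| clozapine | antipsychotic | CYP2D6 | CYP2D6: poor metabolizer | Placeholder fixture guidance (CPIC): clozapine with CYP2D6 poor metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| codeine | opioid | CYP2D6 | CYP2D6: poor metabolizer | Placeholder fixture guidance (CPIC): codeine with CYP2D6 poor metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| desipramine | TCA | CYP2D6 | CYP2D6: poor metabolizer | Placeholder fixture guidance (CPIC): desipramine with CYP2D6 poor metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| doxepin | TCA | CYP2C19, CYP2D6 | CYP2C19: poor metabolizer; CYP2D6: poor metabolizer | Placeholder fixture guidance (CPIC): doxepin with CYP2C19 poor metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| duloxetine | SNRI | CYP2D6 | CYP2D6: poor metabolizer | Placeholder fixture guidance (CPIC): duloxetine with CYP2D6 poor metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| efavirenz | antiretroviral | CYP2B6 | CYP2B6: intermediate metabolizer | Placeholder fixture guidance (CPIC): efavirenz with CYP2B6 intermediate metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| eliglustat | other | CYP2D6 | CYP2D6: poor metabolizer | Placeholder fixture guidance (CPIC): eliglustat with CYP2D6 poor metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| escitalopram | SSRI | CYP2C19 | CYP2C19: poor metabolizer | Placeholder fixture guidance (CPIC): escitalopram with CYP2C19 poor metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| esomeprazole | PPI | CYP2C19 | CYP2C19: poor metabolizer | Placeholder fixture guidance (CPIC): esomeprazole with CYP2C19 poor metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| flecainide | other | CYP2D6 | CYP2D6: poor metabolizer | Placeholder fixture guidance (CPIC): flecainide with CYP2D6 poor metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| fluoxetine | SSRI | CYP2D6 | CYP2D6: poor metabolizer | Placeholder fixture guidance (CPIC): fluoxetine with CYP2D6 poor metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| fluphenazine | antipsychotic | CYP2D6 | CYP2D6: poor metabolizer | Placeholder fixture guidance (CPIC): fluphenazine with CYP2D6 poor metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| flurbiprofen | NSAID | CYP2C9 | CYP2C9: normal metabolizer | Placeholder fixture guidance (CPIC): flurbiprofen with CYP2C9 normal metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | optional | CPIC | no |
| fluvastatin | statin | SLCO1B1 | SLCO1B1: decreased function | Placeholder fixture guidance (CPIC): fluvastatin with SLCO1B1 decreased function. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| fluvoxamine | SSRI | CYP2D6 | CYP2D6: poor metabolizer | Placeholder fixture guidance (CPIC): fluvoxamine with CYP2D6 poor metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| haloperidol | antipsychotic | CYP2D6 | CYP2D6: poor metabolizer | Placeholder fixture guidance (CPIC): haloperidol with CYP2D6 poor metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| hydrocodone | opioid | CYP2D6 | CYP2D6: poor metabolizer | Placeholder fixture guidance (CPIC): hydrocodone with CYP2D6 poor metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| ibuprofen | NSAID | CYP2C9 | CYP2C9: normal metabolizer | Placeholder fixture guidance (CPIC): ibuprofen with CYP2C9 normal metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | optional | CPIC | no |
| iloperidone | antipsychotic | CYP2D6 | CYP2D6: poor metabolizer | Placeholder fixture guidance (CPIC): iloperidone with CYP2D6 poor metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| imipramine | TCA | CYP2C19, CYP2D6 | CYP2C19: poor metabolizer; CYP2D6: poor metabolizer | Placeholder fixture guidance (CPIC): imipramine with CYP2C19 poor metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| lansoprazole | PPI | CYP2C19 | CYP2C19: poor metabolizer | Placeholder fixture guidance (CPIC): lansoprazole with CYP2C19 poor metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| lornoxicam | NSAID | CYP2C9 | CYP2C9: normal metabolizer | Placeholder fixture guidance (CPIC): lornoxicam with CYP2C9 normal metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | optional | CPIC | no |
| meloxicam | NSAID | CYP2C9 | CYP2C9: normal metabolizer | Placeholder fixture guidance (CPIC): meloxicam with CYP2C9 normal metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | optional | CPIC | no |
| mercaptopurine | thiopurine | NUDT15, TPMT | NUDT15: normal metabolizer; TPMT: intermediate metabolizer | Placeholder fixture guidance (CPIC): mercaptopurine with NUDT15 normal metabolizer; TPMT intermediate metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| methylphenidate | stimulant | CYP2D6 | CYP2D6: poor metabolizer | Placeholder fixture guidance (CPIC): methylphenidate with CYP2D6 poor metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| metoprolol | beta-blocker | CYP2D6 | CYP2D6: poor metabolizer | Placeholder fixture guidance (CPIC): metoprolol with CYP2D6 poor metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| mirtazapine | other | CYP2D6 | CYP2D6: poor metabolizer | Placeholder fixture guidance (CPIC): mirtazapine with CYP2D6 poor metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| moclobemide | other | CYP2D6 | CYP2D6: poor metabolizer | Placeholder fixture guidance (CPIC): moclobemide with CYP2D6 poor metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| naproxen | NSAID | CYP2C9 | CYP2C9: normal metabolizer | Placeholder fixture guidance (CPIC): naproxen with CYP2C9 normal metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | optional | CPIC | no |
| nebivolol | beta-blocker | CYP2D6 | CYP2D6: poor metabolizer | Placeholder fixture guidance (CPIC): nebivolol with CYP2D6 poor metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| nortriptyline | TCA | CYP2D6 | CYP2D6: poor metabolizer | Placeholder fixture guidance (CPIC): nortriptyline with CYP2D6 poor metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| odansetron | other | CYP2D6 | CYP2D6: poor metabolizer | Placeholder fixture guidance (CPIC): odansetron with CYP2D6 poor metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| olanzapine | antipsychotic | CYP2D6 | CYP2D6: poor metabolizer | Placeholder fixture guidance (CPIC): olanzapine with CYP2D6 poor metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| omeprazole | PPI | CYP2C19 | CYP2C19: poor metabolizer | Placeholder fixture guidance (CPIC): omeprazole with CYP2C19 poor metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| oxcarbazepine | antiepileptic | HLA-B | HLA-B: *57:01 positive | No recommendation on record for HLA-B *57:01 positive. | none | — | no |
| oxycodone | opioid | CYP2D6 | CYP2D6: poor metabolizer | Placeholder fixture guidance (CPIC): oxycodone with CYP2D6 poor metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| pantoprazole | PPI | CYP2C19 | CYP2C19: poor metabolizer | Placeholder fixture guidance (CPIC): pantoprazole with CYP2C19 poor metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| paroxetine | SSRI | CYP2D6 | CYP2D6: poor metabolizer | Placeholder fixture guidance (CPIC): paroxetine with CYP2D6 poor metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| perphenazine | antipsychotic | CYP2D6 | CYP2D6: poor metabolizer | Placeholder fixture guidance (CPIC): perphenazine with CYP2D6 poor metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| phenytoin | antiepileptic | CYP2C9, HLA-B | CYP2C9: normal metabolizer; HLA-B: *57:01 positive | Placeholder fixture guidance (CPIC): phenytoin with CYP2C9 normal metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | optional | CPIC | no |
| pimozide | antipsychotic | CYP2D6 | CYP2D6: poor metabolizer | Placeholder fixture guidance (CPIC): pimozide with CYP2D6 poor metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| piroxicam | NSAID | CYP2C9 | CYP2C9: normal metabolizer | Placeholder fixture guidance (CPIC): piroxicam with CYP2C9 normal metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | optional | CPIC | no |
| prasugrel | antiplatelet | CYP2C19 | CYP2C19: poor metabolizer | Placeholder fixture guidance (CPIC): prasugrel with CYP2C19 poor metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| propafenone | other | CYP2D6 | CYP2D6: poor metabolizer | Placeholder fixture guidance (CPIC): propafenone with CYP2D6 poor metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| propranolol | beta-blocker | CYP2D6 | CYP2D6: poor metabolizer | Placeholder fixture guidance (CPIC): propranolol with CYP2D6 poor metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| quetiapine | antipsychotic | CYP2D6 | CYP2D6: poor metabolizer | Placeholder fixture guidance (CPIC): quetiapine with CYP2D6 poor metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| risperidone | antipsychotic | CYP2D6 | CYP2D6: poor metabolizer | Placeholder fixture guidance (CPIC): risperidone with CYP2D6 poor metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| rosuvastatin | statin | SLCO1B1 | SLCO1B1: decreased function | Placeholder fixture guidance (CPIC): rosuvastatin with SLCO1B1 decreased function. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| sertraline | SSRI | CYP2C19 | CYP2C19: poor metabolizer | Placeholder fixture guidance (CPIC): sertraline with CYP2C19 poor metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| simvastatin | statin | SLCO1B1 | SLCO1B1: decreased function | Placeholder fixture guidance (CPIC): simvastatin with SLCO1B1 decreased function. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| tacrolimus | immunosuppressant | CYP3A5 | CYP3A5: poor metabolizer | Placeholder fixture guidance (CPIC): tacrolimus with CYP3A5 poor metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| tamoxifen | other | CYP2D6 | CYP2D6: poor metabolizer | Placeholder fixture guidance (CPIC): tamoxifen with CYP2D6 poor metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| tenoxicam | NSAID | CYP2C9 | CYP2C9: normal metabolizer | Placeholder fixture guidance (CPIC): tenoxicam with CYP2C9 normal metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | optional | CPIC | no |
| tetrabenazine | other | CYP2D6 | CYP2D6: poor metabolizer | Placeholder fixture guidance (CPIC): tetrabenazine with CYP2D6 poor metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| thioguanine | thiopurine | NUDT15, TPMT | NUDT15: normal metabolizer; TPMT: intermediate metabolizer | Placeholder fixture guidance (CPIC): thioguanine with NUDT15 normal metabolizer; TPMT intermediate metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| ticagrelor | antiplatelet | CYP2C19 | CYP2C19: poor metabolizer | Placeholder fixture guidance (CPIC): ticagrelor with CYP2C19 poor metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| tramadol | opioid | CYP2D6 | CYP2D6: poor metabolizer | Placeholder fixture guidance (CPIC): tramadol with CYP2D6 poor metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| trimipramine | TCA | CYP2C19, CYP2D6 | CYP2C19: poor metabolizer; CYP2D6: poor metabolizer | Placeholder fixture guidance (CPIC): trimipramine with CYP2C19 poor metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| tropisetron | other | CYP2D6 | CYP2D6: poor metabolizer | Placeholder fixture guidance (CPIC): tropisetron with CYP2D6 poor metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| venlafaxine | SNRI | CYP2D6 | CYP2D6: poor metabolizer | Placeholder fixture guidance (CPIC): venlafaxine with CYP2D6 poor metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| voriconazole | antifungal | CYP2C19 | CYP2C19: poor metabolizer | Placeholder fixture guidance (CPIC): voriconazole with CYP2C19 poor metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| vortioxetine | SSRI | CYP2D6 | CYP2D6: poor metabolizer | Placeholder fixture guidance (CPIC): vortioxetine with CYP2D6 poor metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| warfarin | anticoagulant | CYP2C9, VKORC1 | CYP2C9: normal metabolizer; VKORC1: increased warfarin sensitivity | Placeholder fixture guidance (CPIC): warfarin with CYP2C9 normal metabolizer; VKORC1 increased warfarin sensitivity. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| zuclopenthixol | antipsychotic | CYP2D6 | CYP2D6: poor metabolizer | Placeholder fixture guidance (CPIC): zuclopenthixol with CYP2D6 poor metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |

## Medications Being Considered

| Drug | Class | Gene(s) | Phenotype(s) | Recommendation | Strength | Source | Actionable |
| --- | --- | --- | --- | --- | --- | --- | --- |
| codeine | opioid | CYP2D6 | CYP2D6: poor metabolizer | Placeholder fixture guidance (CPIC): codeine with CYP2D6 poor metabolizer. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |
| warfarin | anticoagulant | CYP2C9, VKORC1 | CYP2C9: normal metabolizer; VKORC1: increased warfarin sensitivity | Placeholder fixture guidance (CPIC): warfarin with CYP2C9 normal metabolizer; VKORC1 increased warfarin sensitivity. Synthetic demonstration text — consult the cited source guideline for clinical wording. [placeholder] | strong | CPIC | yes |

Not supported by the knowledge base: notadrug

## Disclaimer

This report is intended for interpretation by a licensed physician or other licensed healthcare professional, who retains ultimate responsibility for all therapeutic decisions in light of the individual characteristics of the patient and the drugs prescribed. The generating software accepts no responsibility for modification or redistribution of this report and is not liable for actions taken on the basis of its contents, or for any inaccuracies, errors, or omissions. Recommendations flagged [placeholder] carry synthetic demonstration text, not clinical guidance.
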