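section,band,count
total,total,216362
sex,Male,94264
sex,Female,100658
sex,Unknown,21440
age,<18,4376
age,18-<65,66722
age,65-<85,68625
age,>=85,9535
age,Unknown,67104
weight,<50,7004
weight,50-<100,44470
weight,>=100,11190
weight,Unknown,153698
occupation,Healthcare professional,134873
occupation,Non-healthcare professional,70687
occupation,Unknown,10802
country,United States,99942
country,Japan,14919
country,France,11016
country,Canada,8457
country,Germany,8137
country,United Kingdom,6939
country,Others,66952
outcome,Hospitalization,88164
outcome,Death,63442
outcome,Other Serious Outcome,42172
outcome,Life-threatening,14422
outcome,Disability,926
outcome,Unknown,7236
database,All reports,17379609
database,HF reports,240050
database,AHF reports,5971
database,Top-50 HF events,110359
database,HF TTO usable,62186
database,AHF TTO usable,2277
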