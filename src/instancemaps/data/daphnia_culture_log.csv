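date,day_of_culture,count_jar1,count_jar2,count_jar3,count_jar4,count_jar5,count_jar6,offspring_jar1,offspring_jar2,offspring_jar3,offspring_jar4,offspring_jar5,offspring_jar6,food_ml,medium_change,comments
02/01/24,1,12,12,12,12,12,12,,,,,,,0.75,x,
03/01/24,2,12,12,12,12,12,12,,,,,,,0.5,,
04/01/24,3,12,12,12,12,12,12,,,,,,,0.75,,
05/01/24,4,12,11,12,12,12,12,,,,,,,1,,
06/01/24,5,12,11,12,12,12,12,,,,,,,1,x,
07/01/24,6,12,11,12,12,12,12,,,,,,,2,,
08/01/24,7,12,11,12,12,12,12,,,,,,,0,,
09/01/24,8,12,11,12,12,12,12,,,,,,,1.5,x,
10/01/24,9,12,11,12,12,12,12,,,,,,,1.5,,
11/01/24,10,12,11,12,12,12,12,,,,,,,1.5,,eggs in brood pouch
12/01/24,11,12,11,12,12,11,12,x,x,x,,x,x,1.5,x,first brood
13/01/24,12,12,11,12,12,11,12,,,,x,,,3,,
14/01/24,13,12,11,12,12,11,12,,,,,,,0,,
15/01/24,14,12,11,12,12,11,12,x,x,x,,x,x,1.5,x,
16/01/24,15,12,11,12,12,11,12,,,,x,,,1.5,,
17/01/24,16,12,11,12,12,11,12,,,,,,,1.5,,
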