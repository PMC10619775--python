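label,total_n,level,n,printed_pct,provenance
Total,273213121,no_access,5038797,1.8,"Table 1, Total row"
Total,273213121,below_average,73095752,26.8,"Table 1, Total row"
Total,273213121,average,111551394,40.8,"Table 1, Total row"
Total,273213121,above_average,83527178,30.6,"Table 1, Total row"
AI/AN,2557951,no_access,321170,12.6,"Table 1, AI/AN row"
AI/AN,2557951,below_average,729540,28.5,"Table 1, AI/AN row"
AI/AN,2557951,average,849815,33.2,"Table 1, AI/AN row"
AI/AN,2557951,above_average,657426,25.7,"Table 1, AI/AN row"
Asian,16430033,no_access,120747,0.7,"Table 1, Asian row"
Asian,16430033,below_average,3792732,23.1,"Table 1, Asian row"
Asian,16430033,average,8603441,52.4,"Table 1, Asian row"
Asian,16430033,above_average,3913113,23.8,"Table 1, Asian row"
Black,34282392,no_access,198477,0.6,"Table 1, Black row"
Black,34282392,below_average,5670717,16.5,"Table 1, Black row"
Black,34282392,average,13739382,40.1,"Table 1, Black row"
Black,34282392,above_average,14673816,42.8,"Table 1, Black row"
Hispanic,46262773,no_access,655254,1.4,"Table 1, Hispanic row"
Hispanic,46262773,below_average,10636518,23.0,"Table 1, Hispanic row"
Hispanic,46262773,average,22115302,47.8,"Table 1, Hispanic row"
Hispanic,46262773,above_average,12855699,27.8,"Table 1, Hispanic row"
Pacific Islander,518017,no_access,27176,5.2,"Table 1, Pacific Islander row"
Pacific Islander,518017,below_average,181319,35.0,"Table 1, Pacific Islander row"
Pacific Islander,518017,average,232475,44.9,"Table 1, Pacific Islander row"
Pacific Islander,518017,above_average,77047,14.9,"Table 1, Pacific Islander row"
White,194539646,no_access,3995993,2.1,"Table 1, White row"
White,194539646,below_average,56345774,29.0,"Table 1, White row"
White,194539646,average,76572788,39.4,"Table 1, White row"
White,194539646,above_average,57625091,29.6,"Table 1, White row"
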