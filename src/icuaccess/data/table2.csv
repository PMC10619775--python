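label,total_n,printed_share_pct,level,n,printed_pct,provenance
Total,273213121,,no_access,5038797,1.8,"Table 2, Total row"
Total,273213121,,below_average,73095752,26.8,"Table 2, Total row"
Total,273213121,,average,111551394,40.8,"Table 2, Total row"
Total,273213121,,above_average,96720985,35.4,"Table 2, Total row (inconsistent with Table 1)"
Principle Urban Centers,17999658,6.6,no_access,34424,0.2,"Table 2, Principle Urban Centers row"
Principle Urban Centers,17999658,6.6,below_average,2054474,11.4,"Table 2, Principle Urban Centers row"
Principle Urban Centers,17999658,6.6,average,10692960,59.4,"Table 2, Principle Urban Centers row"
Principle Urban Centers,17999658,6.6,above_average,5217800,29.0,"Table 2, Principle Urban Centers row"
Urban Periphery,48286246,17.7,no_access,327465,0.7,"Table 2, Urban Periphery row"
Urban Periphery,48286246,17.7,below_average,8759019,18.1,"Table 2, Urban Periphery row"
Urban Periphery,48286246,17.7,average,22855529,47.3,"Table 2, Urban Periphery row"
Urban Periphery,48286246,17.7,above_average,16344233,33.8,"Table 2, Urban Periphery row"
Metro Cities,45323815,16.6,no_access,413402,0.9,"Table 2, Metro Cities row"
Metro Cities,45323815,16.6,below_average,10626712,23.4,"Table 2, Metro Cities row"
Metro Cities,45323815,16.6,average,16964404,37.4,"Table 2, Metro Cities row"
Metro Cities,45323815,16.6,above_average,17319297,38.2,"Table 2, Metro Cities row"
Suburban Periphery,103116473,37.7,no_access,974191,0.9,"Table 2, Suburban Periphery row"
Suburban Periphery,103116473,37.7,below_average,24229599,23.5,"Table 2, Suburban Periphery row"
Suburban Periphery,103116473,37.7,average,38953952,37.8,"Table 2, Suburban Periphery row"
Suburban Periphery,103116473,37.7,above_average,38958731,37.8,"Table 2, Suburban Periphery row"
Semirural,24900378,9.1,no_access,839346,3.4,"Table 2, Semirural row"
Semirural,24900378,9.1,below_average,8180983,32.9,"Table 2, Semirural row"
Semirural,24900378,9.1,average,8367029,33.6,"Table 2, Semirural row"
Semirural,24900378,9.1,above_average,7513020,30.2,"Table 2, Semirural row"
Rural,46242302,16.9,no_access,2426233,5.2,"Table 2, Rural row"
Rural,46242302,16.9,below_average,19053063,41.2,"Table 2, Rural row"
Rural,46242302,16.9,average,13490093,29.2,"Table 2, Rural row"
Rural,46242302,16.9,above_average,11272913,24.4,"Table 2, Rural row"
No Data,538056,0.2,no_access,23736,4.4,"Table 2, No Data row"
No Data,538056,0.2,below_average,191902,35.7,"Table 2, No Data row"
No Data,538056,0.2,average,227427,42.3,"Table 2, No Data row"
No Data,538056,0.2,above_average,94991,17.7,"Table 2, No Data row"
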