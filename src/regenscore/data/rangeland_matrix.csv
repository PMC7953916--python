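location,ivermectin,stocking_density,rotation_frequency,rest_period,composite_printed
"Bruce, SD",1,0,0,0,1
"Castlewood, SD",1,2,1,2,6
"Clear Lake, SD",2,2,2,2,8
"Estelline, SD",1,1,1,2,5
"Estelline, SD",0,1,0,0,1
"Flandreau, SD",0,0,0,0,0
"Gary, SD",2,2,2,2,8
"Goodwin, SD",2,2,2,2,8
"Madison, SD",0,1,1,2,4
"Milbank, SD",1,1,1,2,5
"Milbank, SD",0,0,0,2,2
"Sioux Falls, SD",2,2,2,2,8
"Summit, SD",1,1,1,2,5
"Thomas, SD",1,1,2,2,6
"Twin Brooks, SD",2,2,1,2,7
"Volga, SD",0,0,0,0,0
"Hayti, SD",0,0,0,0,0
"Hayti, SD",0,0,0,0,0
"Strandburg, SD",0,0,0,0,0
"Estelline, SD",0,0,0,0,0
"Watertown, SD",1,2,2,2,7
"Hayti, SD",1,1,2,2,6
"Estelline, SD",2,1,2,2,7
"Gary, SD",2,1,2,2,7
"Goodwin, SD",1,1,2,2,6
"Tuttle, ND",1,0,0,0,1
"Tuttle, ND",0,0,0,0,0
"Wing, ND",0,0,0,0,0
"Moffit, ND",1,0,0,0,1
"Fort Rice, ND",2,2,2,2,8
"ND7; Wing, ND",2,1,2,2,7
"Bismarck, ND",2,2,2,2,8
"Wing, ND",2,2,2,2,8
"Moffit, ND",2,2,2,2,8
"Summit, SD",0,0,2,2,4
"Summit, SD",0,0,0,0,0
"Milbank, SD",2,1,1,2,6
"Milbank, SD",0,0,0,0,0
"Watertown, SD",2,2,2,2,8
"Castlewood, SD",0,0,0,0,0
"Summit, SD",2,0,2,2,6
"Milbank, SD",0,0,0,0,0
"Castlewood, SD",2,2,2,2,8
"Castlewood, SD",0,0,1,2,2
"Sheldon, ND",0,1,2,2,5
"Sheldon, ND",0,0,0,0,0
"Napoleon, ND",0,2,2,2,6
"Napoleon, ND",0,0,0,0,0
"Ellendale, ND",2,2,2,2,8
"Forbes, ND",1,0,1,2,4
"Forbes, ND",2,2,2,2,8
"Berlin, ND",0,1,1,0,2
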