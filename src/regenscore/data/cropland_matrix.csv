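location,system,fertilizers,herbicides,fungicides,insecticides,tillage,cover_crops,field_margins,organic_amendments,grazers,composite_printed
"Merced, CA",cropland_full,1,1,1,1,0,1,1,1,0,7
"Butte, CA",cropland_full,1,1,0,1,1,1,1,1,0,7
"Merced, CA",cropland_full,1,1,1,1,1,1,1,1,0,8
"Merced, CA",cropland_full,1,1,1,1,1,1,1,1,0,8
"Yolo, CA",cropland_full,1,1,0,1,0,1,1,1,1,7
"Butte, CA",cropland_full,0,0,0,0,1,1,0,1,0,3
"Butte, CA",cropland_full,0,0,0,0,1,0,0,0,0,1
"Yolo, CA",cropland_full,0,0,0,0,1,0,0,0,0,1
"Yolo, CA",cropland_full,0,0,0,0,1,0,0,0,0,1
"Butte, CA",cropland_full,1,1,0,1,1,1,1,1,0,7
"Merced, CA",cropland_full,1,1,0,1,1,1,0,1,0,6
"Merced, CA",cropland_full,0,0,0,0,1,0,0,0,0,1
"Yolo, CA",cropland_full,1,1,1,1,1,1,0,0,1,7
"Merced, CA",cropland_full,0,0,0,0,1,0,0,1,0,2
"Merced, CA",cropland_full,0,0,0,0,1,0,0,1,0,2
"Merced, CA",cropland_full,0,0,0,0,1,1,0,1,0,3
"Bladen, NE",cropland_corn,0,0,,0,0,0,,,0,0
"York, NE",cropland_corn,0,0,,0,0,0,,,0,0
"Bismarck, ND",cropland_corn,0,0,,0,1,0,,,0,1
"Bismarck, ND",cropland_corn,0,0,,0,1,0,,,0,1
"White, SD",cropland_corn,0,0,,0,0,0,,,0,0
"Pipestone, MN",cropland_corn,0,0,,0,0,0,,,0,0
"Toronto, SD",cropland_corn,0,0,,0,0,0,,,0,0
"Gary, SD",cropland_corn,0,0,,0,0,0,,,0,0
"Arlington, SD",cropland_corn,0,0,,0,0,0,,,0,0
"Lake Norden, SD",cropland_corn,0,0,,0,0,0,,,0,0
"Bladen, NE",cropland_corn,1,0,,1,1,1,,,0,4
"York, NE",cropland_corn,1,0,,1,1,1,,,0,4
"Bismarck, ND",cropland_corn,0,1,,1,1,1,,,1,5
"Bismarck, ND",cropland_corn,1,0,,1,1,1,,,1,5
"White, SD",cropland_corn,1,1,,1,0,1,,,0,4
"Pipestone, MN",cropland_corn,1,1,,1,0,1,,,0,4
"Toronto, SD",cropland_corn,1,0,,0,1,1,,,0,3
"Gary, SD",cropland_corn,1,1,,1,0,1,,,1,4
"Arlington, SD",cropland_corn,1,0,,1,1,1,,,1,5
"Lake Norden, SD",cropland_corn,1,0,,1,1,1,,,0,4
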