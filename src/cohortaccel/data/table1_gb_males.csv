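age_band,1895-99,1900-04,1905-09,1910-14,1915-19,1920-24,1925-29,1930-34,1935-39,1940-44,1945-49,1950-54,1955-59,1960-64,1965-69,1970-74,1975-79
25-29,,,,,,,,,,,,1.5,2.0,2.9,3.4,4.1,4.7
30-34,,,,,,,,,,,2.2,2.9,4.0,4.7,5.7,6.8,7.4
35-39,,,,,,,,,,3.2,4.2,5.4,6.1,7.2,9.5,10.5,10.1
40-44,,,,,,,,,3.7,5.2,7.4,7.7,9.4,12.4,14.4,14.2,
45-49,,,,,,,,4.2,5.9,8.5,10.2,11.8,14.7,17.0,20.0,,
50-54,,,,,,,4.8,7.0,9.9,12.5,14.9,18.1,22.0,24.2,,,
55-59,,,,,,5.0,7.4,11.4,15.4,17.9,24.3,28.7,30.8,,,,
60-64,,,,,6.0,8.9,13.2,16.9,22.6,31.3,41.1,44.1,,,,,
65-69,,,,6.5,9.7,14.2,19.5,26.1,36.8,50.7,57.1,,,,,,
70-74,,,7.3,10.4,15.4,20.9,28.8,44.3,63.6,73.8,,,,,,,
75-79,,8.9,11.9,18.5,24.1,33.6,47.5,71.4,90.8,,,,,,,,
80-84,9.5,13.5,19.4,29.1,41.6,56.3,79.4,103.5,,,,,,,,,
85+,17.0,24.6,33.3,43.9,63.2,90.1,114.9,,,,,,,,,,
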