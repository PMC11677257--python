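year,item,quantity,unit
2006,alcohol,30.7,kg/person/year
2006,dairy,113.4,kg/person/year
2006,eggs,117.8,units/person/year
2006,fats,10.8,kg/person/year
2006,fish,24.3,kg/person/year
2006,fruits,76.9,kg/person/year
2006,grains,53.1,kg/person/year
2006,legumes,13.0,kg/person/year
2006,potatoes,27.6,kg/person/year
2006,poultry,11.7,kg/person/year
2006,red_meat,39.9,kg/person/year
2006,sugar,4.6,kg/person/year
2006,vegetables,42.7,kg/person/year
2007,alcohol,33.5,kg/person/year
2007,dairy,116.7,kg/person/year
2007,eggs,125.0,units/person/year
2007,fats,7.8,kg/person/year
2007,fish,24.7,kg/person/year
2007,fruits,81.6,kg/person/year
2007,grains,56.0,kg/person/year
2007,legumes,13.8,kg/person/year
2007,potatoes,21.2,kg/person/year
2007,poultry,13.3,kg/person/year
2007,red_meat,40.8,kg/person/year
2007,sugar,5.0,kg/person/year
2007,vegetables,44.7,kg/person/year
2008,alcohol,34.0,kg/person/year
2008,dairy,114.8,kg/person/year
2008,eggs,126.8,units/person/year
2008,fats,11.3,kg/person/year
2008,fish,23.9,kg/person/year
2008,fruits,77.9,kg/person/year
2008,grains,55.1,kg/person/year
2008,legumes,13.7,kg/person/year
2008,potatoes,29.9,kg/person/year
2008,poultry,13.2,kg/person/year
2008,red_meat,43.2,kg/person/year
2008,sugar,4.9,kg/person/year
2008,vegetables,45.0,kg/person/year
2009,alcohol,34.7,kg/person/year
2009,dairy,114.6,kg/person/year
2009,eggs,129.7,units/person/year
2009,fats,11.2,kg/person/year
2009,fish,23.8,kg/person/year
2009,fruits,77.9,kg/person/year
2009,grains,55.5,kg/person/year
2009,legumes,13.7,kg/person/year
2009,potatoes,31.1,kg/person/year
2009,poultry,13.3,kg/person/year
2009,red_meat,40.8,kg/person/year
2009,sugar,5.2,kg/person/year
2009,vegetables,45.4,kg/person/year
2010,alcohol,33.7,kg/person/year
2010,dairy,111.1,kg/person/year
2010,eggs,127.9,units/person/year
2010,fats,10.6,kg/person/year
2010,fish,23.1,kg/person/year
2010,fruits,81.2,kg/person/year
2010,grains,54.3,kg/person/year
2010,legumes,14.0,kg/person/year
2010,potatoes,30.1,kg/person/year
2010,poultry,13.4,kg/person/year
2010,red_meat,39.5,kg/person/year
2010,sugar,4.8,kg/person/year
2010,vegetables,46.3,kg/person/year
2011,alcohol,34.1,kg/person/year
2011,dairy,110.7,kg/person/year
2011,eggs,130.1,units/person/year
2011,fats,10.6,kg/person/year
2011,fish,22.7,kg/person/year
2011,fruits,79.1,kg/person/year
2011,grains,54.0,kg/person/year
2011,legumes,13.6,kg/person/year
2011,potatoes,27.3,kg/person/year
2011,poultry,13.3,kg/person/year
2011,red_meat,38.8,kg/person/year
2011,sugar,4.7,kg/person/year
2011,vegetables,47.2,kg/person/year
2012,alcohol,34.2,kg/person/year
2012,dairy,110.6,kg/person/year
2012,eggs,137.5,units/person/year
2012,fats,10.5,kg/person/year
2012,fish,22.4,kg/person/year
2012,fruits,77.9,kg/person/year
2012,grains,52.6,kg/person/year
2012,legumes,13.6,kg/person/year
2012,potatoes,28.4,kg/person/year
2012,poultry,14.2,kg/person/year
2012,red_meat,39.5,kg/person/year
2012,sugar,4.8,kg/person/year
2012,vegetables,46.0,kg/person/year
2013,alcohol,33.8,kg/person/year
2013,dairy,109.3,kg/person/year
2013,eggs,136.2,units/person/year
2013,fats,9.5,kg/person/year
2013,fish,22.1,kg/person/year
2013,fruits,76.7,kg/person/year
2013,grains,52.3,kg/person/year
2013,legumes,13.1,kg/person/year
2013,potatoes,28.8,kg/person/year
2013,poultry,14.1,kg/person/year
2013,red_meat,38.5,kg/person/year
2013,sugar,4.7,kg/person/year
2013,vegetables,47.7,kg/person/year
2014,alcohol,34.2,kg/person/year
2014,dairy,106.9,kg/person/year
2014,eggs,133.9,units/person/year
2014,fats,9.6,kg/person/year
2014,fish,21.3,kg/person/year
2014,fruits,75.8,kg/person/year
2014,grains,51.8,kg/person/year
2014,legumes,13.1,kg/person/year
2014,potatoes,28.8,kg/person/year
2014,poultry,13.8,kg/person/year
2014,red_meat,38.5,kg/person/year
2014,sugar,4.4,kg/person/year
2014,vegetables,46.7,kg/person/year
2015,alcohol,34.9,kg/person/year
2015,dairy,106.9,kg/person/year
2015,eggs,135.1,units/person/year
2015,fats,9.1,kg/person/year
2015,fish,21.3,kg/person/year
2015,fruits,80.2,kg/person/year
2015,grains,50.6,kg/person/year
2015,legumes,13.7,kg/person/year
2015,potatoes,27.2,kg/person/year
2015,poultry,13.7,kg/person/year
2015,red_meat,38.2,kg/person/year
2015,sugar,4.2,kg/person/year
2015,vegetables,47.3,kg/person/year
2016,alcohol,36.8,kg/person/year
2016,dairy,98.7,kg/person/year
2016,eggs,127.2,units/person/year
2016,fats,8.7,kg/person/year
2016,fish,20.5,kg/person/year
2016,fruits,79.6,kg/person/year
2016,grains,75.5,kg/person/year
2016,legumes,11.5,kg/person/year
2016,potatoes,24.1,kg/person/year
2016,poultry,14.0,kg/person/year
2016,red_meat,34.8,kg/person/year
2016,sugar,3.8,kg/person/year
2016,vegetables,46.6,kg/person/year
2017,alcohol,36.9,kg/person/year
2017,dairy,97.0,kg/person/year
2017,eggs,127.4,units/person/year
2017,fats,8.3,kg/person/year
2017,fish,19.3,kg/person/year
2017,fruits,80.3,kg/person/year
2017,grains,73.7,kg/person/year
2017,legumes,11.5,kg/person/year
2017,potatoes,24.4,kg/person/year
2017,poultry,13.4,kg/person/year
2017,red_meat,33.3,kg/person/year
2017,sugar,3.7,kg/person/year
2017,vegetables,45.6,kg/person/year
2018,alcohol,35.9,kg/person/year
2018,dairy,93.4,kg/person/year
2018,eggs,126.5,units/person/year
2018,fats,8.9,kg/person/year
2018,fish,19.1,kg/person/year
2018,fruits,80.9,kg/person/year
2018,grains,72.4,kg/person/year
2018,legumes,11.0,kg/person/year
2018,potatoes,22.2,kg/person/year
2018,poultry,13.5,kg/person/year
2018,red_meat,34.3,kg/person/year
2018,sugar,3.5,kg/person/year
2018,vegetables,44.3,kg/person/year
2019,alcohol,35.5,kg/person/year
2019,dairy,92.3,kg/person/year
2019,eggs,125.4,units/person/year
2019,fats,8.3,kg/person/year
2019,fish,18.7,kg/person/year
2019,fruits,78.1,kg/person/year
2019,grains,72.4,kg/person/year
2019,legumes,11.2,kg/person/year
2019,potatoes,21.7,kg/person/year
2019,poultry,13.4,kg/person/year
2019,red_meat,33.9,kg/person/year
2019,sugar,3.3,kg/person/year
2019,vegetables,43.3,kg/person/year
2020,alcohol,41.2,kg/person/year
2020,dairy,97.6,kg/person/year
2020,eggs,133.5,units/person/year
2020,fats,8.2,kg/person/year
2020,fish,19.5,kg/person/year
2020,fruits,76.8,kg/person/year
2020,grains,70.0,kg/person/year
2020,legumes,12.3,kg/person/year
2020,potatoes,22.7,kg/person/year
2020,poultry,13.7,kg/person/year
2020,red_meat,33.9,kg/person/year
2020,sugar,3.5,kg/person/year
2020,vegetables,47.0,kg/person/year
2021,alcohol,37.7,kg/person/year
2021,dairy,101.6,kg/person/year
2021,eggs,140.4,units/person/year
2021,fats,8.7,kg/person/year
2021,fish,20.5,kg/person/year
2021,fruits,81.3,kg/person/year
2021,grains,71.8,kg/person/year
2021,legumes,12.5,kg/person/year
2021,potatoes,21.7,kg/person/year
2021,poultry,14.1,kg/person/year
2021,red_meat,34.6,kg/person/year
2021,sugar,3.2,kg/person/year
2021,vegetables,46.8,kg/person/year
2022,alcohol,38.7,kg/person/year
2022,dairy,100.8,kg/person/year
2022,eggs,139.5,units/person/year
2022,fats,8.9,kg/person/year
2022,fish,19.6,kg/person/year
2022,fruits,74.9,kg/person/year
2022,grains,73.6,kg/person/year
2022,legumes,12.3,kg/person/year
2022,potatoes,21.3,kg/person/year
2022,poultry,14.3,kg/person/year
2022,red_meat,34.2,kg/person/year
2022,sugar,3.0,kg/person/year
2022,vegetables,44.8,kg/person/year
2023,alcohol,37.2,kg/person/year
2023,dairy,99.7,kg/person/year
2023,eggs,150.0,units/person/year
2023,fats,7.8,kg/person/year
2023,fish,19.0,kg/person/year
2023,fruits,75.2,kg/person/year
2023,grains,72.6,kg/person/year
2023,legumes,12.8,kg/person/year
2023,potatoes,22.6,kg/person/year
2023,poultry,15.2,kg/person/year
2023,red_meat,35.5,kg/person/year
2023,sugar,3.3,kg/person/year
2023,vegetables,44.3,kg/person/year
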